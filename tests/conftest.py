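import numpy as np
import pytest

from repeatscape.seqio import GenomeInterval, SequenceRecord, SequenceSet
from repeatscape.simulate import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_set():
    return SequenceSet([
        SequenceRecord("s1", "ACGTACGTAA"),
        SequenceRecord("s2", "GGGGCCCCNNACGT"),
        SequenceRecord("s3", "ATATATATATATATATATATATATATATAT"),
    ])


def random_intervals(rng, n, seq_lens):
    """n random intervals over the given {seq_id: length} map."""
    ids = sorted(seq_lens)
    out = []
    for _ in range(n):
        sid = ids[rng.integers(len(ids))]
        length = seq_lens[sid]
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, length + 1))
        out.append(GenomeInterval(sid, start, end))
    return out


def mask_coverage(intervals, seq_lens):
    """Brute-force per-base boolean-mask union size (oracle)."""
    masks = {sid: np.zeros(n, dtype=bool) for sid, n in seq_lens.items()}
    for iv in intervals:
        masks[iv.seq_id][iv.start:iv.end] = True
    return int(sum(m.sum() for m in masks.values()))


@pytest.fixture
def background():
    def make(n, seed=0, gc=0.38):
        return random_sequence(n, np.random.default_rng(seed), gc)
    return make
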