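"""Tandem repeat detection, classification and summary statistics.

Arrays with repeat units (periods) of 2-500 bp are detected in-house or
ingested from Tandem Repeats Finder ``.dat`` output, overlap-filtered by
alignment score, binned into microsatellites (2-8 bp), minisatellites
(9-100 bp) and satellites (>100 bp), and summarized (loci, summed copy
number, distinct canonical motifs, total length and percent of the
sequence set).

The in-house detector proposes candidate periods from self-match densities
at each lag and verifies each candidate by a wraparound local alignment of
the window against its period consensus under the Tandem Repeats Finder
default scoring convention (match +2, mismatch -7, indel -7, minimum
reported score 50, minimum 1.8 copies). Mononucleotide (period 1) repeats
are not considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import (GenomeInterval, SequenceRecord, SequenceSet, revcomp)

logger = logging.getLogger(__name__)

MICRO_SUB_BINS = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa",
                  7: "hepta", 8: "octa"}
MINI_SUB_BINS = [(9, 30), (31, 50), (51, 70), (71, 100)]
SAT_SUB_BINS = [(101, 200), (201, 300), (301, 400), (401, 500)]


@dataclass(frozen=True)
class TandemParams:
    """Detection parameters (Tandem Repeats Finder default convention)."""

    min_period: int = 2
    max_period: int = 500
    match: int = 2
    mismatch: int = -7
    indel: int = -7
    min_score: int = 50
    min_copies: float = 1.8


@dataclass
class TandemArray:
    """One tandem repeat locus."""

    interval: GenomeInterval
    period_size: int
    copy_number: float
    consensus_motif: str
    percent_matches: float
    score: float
    at_fraction: float

    def __post_init__(self) -> None:
        if not 2 <= self.period_size <= 500:
            raise ValueError(f"period {self.period_size} outside [2, 500]")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def at_rich(self) -> bool:
        """A%+T% strictly above 60% on the array's genomic span."""
        return self.at_fraction > 0.60


def classify_period(period: int) -> tuple[str, str]:
    """(class, sub-bin) of a period size: micro 2-8, mini 9-100, sat >100."""
    if 2 <= period <= 8:
        return "micro", MICRO_SUB_BINS[period]
    if 9 <= period <= 100:
        for lo, hi in MINI_SUB_BINS:
            if lo <= period <= hi:
                return "mini", f"{lo}-{hi}"
    if period > 100:
        for lo, hi in SAT_SUB_BINS[:-1]:
            if lo <= period <= hi:
                return "sat", f"{lo}-{hi}"
        return "sat", ">400"
    raise ValueError(f"period {period} outside [2, 500]")


# ---------------------------------------------------------------------------
# canonical motifs


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the motif or its reverse
    complement; groups e.g. AT/TA and the six AT-rich trinucleotides
    ATT/AAT/ATA/TTA/TAT/TAA into single classes."""
    if len(motif) < 2:
        raise ValueError("motif length must be >= 2")
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    return min(_rotations(motif) + _rotations(revcomp(motif)))


def primitive_period(motif: str) -> int:
    """Smallest d dividing len(motif) with motif = (motif[:d]) * k."""
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return d
    return n


# ---------------------------------------------------------------------------
# TRF .dat ingestion


def read_trf_dat(path: str | Path) -> list[TandemArray]:
    """Read Tandem Repeats Finder ``.dat`` output.

    Data lines (start end period copies consensus_size pct_match pct_indel
    score A C G T entropy consensus array_sequence) are grouped under
    ``Sequence:`` headers; 1-based inclusive coordinates are converted to
    the internal 0-based half-open convention. Period-1 records are
    dropped with a logged count.
    """
    arrays: list[TandemArray] = []
    seq_id = None
    n_mono = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                seq_id = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Tandem", "Program", "Version",
                                "Parameters:")):
                continue
            fields = line.split()
            if len(fields) < 15 or not fields[0].isdigit():
                # header/parameter noise lines are tolerated only before
                # the first record of a sequence block
                if seq_id is None:
                    continue
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            if seq_id is None:
                raise ValueError(f"{path}: data line {lineno} before any "
                                 "'Sequence:' header")
            try:
                start, end = int(fields[0]), int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                pct_match = float(fields[5])
                score = float(fields[7])
                consensus = fields[13]
                array_seq = fields[14]
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed line {lineno}: {line!r}"
                ) from exc
            if period == 1:
                n_mono += 1
                continue
            if period > 500:
                continue  # outside the considered period range
            at = (array_seq.count("A") + array_seq.count("T")) / len(array_seq)
            arrays.append(TandemArray(
                interval=GenomeInterval(seq_id, start - 1, end),
                period_size=period,
                copy_number=round(copies, 1),
                consensus_motif=consensus,
                percent_matches=pct_match / 100.0,
                score=score,
                at_fraction=at,
            ))
    if n_mono:
        logger.info("dropped %d mononucleotide (period 1) records", n_mono)
    return arrays


# ---------------------------------------------------------------------------
# in-house detection


def _phase_consensus(window: np.ndarray, period: int) -> np.ndarray:
    """Majority base per phase class of the window (phase 0 = window[0])."""
    consensus = np.empty(period, dtype=np.uint8)
    for j in range(period):
        col = window[j::period]
        vals, counts = np.unique(col, return_counts=True)
        consensus[j] = vals[np.argmax(counts)]
    return consensus


def _wraparound_local(window: np.ndarray, consensus: np.ndarray,
                      params: TandemParams):
    """Local alignment of the window against the cyclic consensus.

    Returns (score, win_start, win_end, matches, columns, consumed) of the
    best-scoring path, or None if the best score is below ``min_score``.
    Gap penalties are linear (per indel residue), matching the detector's
    scoring convention.
    """
    n, p = len(window), len(consensus)
    gap = params.indel
    sub_match, sub_mis = params.match, params.mismatch
    H = np.zeros((n + 1, p), dtype=np.int32)
    idx2 = np.arange(2 * p, dtype=np.int64)
    decay2 = (-gap) * idx2
    for i in range(1, n + 1):
        prev = H[i - 1]
        sub = np.where(consensus == window[i - 1], sub_match, sub_mis)
        cur = np.maximum(np.roll(prev, 1) + sub, prev + gap)
        np.maximum(cur, 0, out=cur)
        # within-row (gap over consensus) propagation around the circle
        t = np.concatenate([cur, cur]) + decay2
        np.maximum.accumulate(t, out=t)
        t -= decay2
        cur = np.maximum(t[:p], t[p:])
        np.maximum(cur, 0, out=cur)
        H[i] = cur
    best_flat = int(np.argmax(H))
    best_i, best_j = divmod(best_flat, p)
    best_score = int(H[best_i, best_j])
    if best_score < params.min_score:
        return None
    # traceback
    i, j = best_i, best_j
    matches = columns = consumed = 0
    while i > 0 and H[i, j] > 0:
        jm = (j - 1) % p
        sub = sub_match if consensus[j] == window[i - 1] else sub_mis
        if H[i, j] == H[i - 1, jm] + sub:
            matches += int(sub == sub_match)
            columns += 1
            consumed += 1
            i, j = i - 1, jm
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        elif H[i, j] == H[i, jm] + gap:
            columns += 1
            consumed += 1
            j = jm
        else:  # path start (local reset)
            break
    return best_score, i, best_i, matches, columns, consumed


_MAX_DP_CELLS = 12_000_000


def _candidate_regions(arr: np.ndarray, period: int,
                       window: int = 24, min_frac: float = 0.75):
    """Spans where the self-match density at lag ``period`` is high."""
    eq = arr[period:] == arr[:-period]
    m = len(eq)
    if m < 8:
        return []
    if m <= window:
        if eq.sum() >= max(6, int(min_frac * m)):
            return [(0, m)]
        return []
    cs = np.concatenate([[0], np.cumsum(eq)])
    win = cs[window:] - cs[:-window]
    hits = np.flatnonzero(win >= int(min_frac * window))
    if len(hits) == 0:
        return []
    spans = []
    start = prev = int(hits[0])
    for h in hits[1:]:
        h = int(h)
        if h - prev > window:
            spans.append((start, prev + window))
            start = h
        prev = h
    spans.append((start, prev + window))
    return spans


def _covered(accepted: list[TandemArray], s0: int, e0: int,
             period: int) -> bool:
    """True when an accepted array of a divisor period spans the window."""
    for arr in accepted:
        if period % arr.period_size == 0 and arr.period_size < period:
            ov = min(arr.interval.end, e0) - max(arr.interval.start, s0)
            if ov >= 0.9 * (e0 - s0):
                return True
    return False


def detect_tandem(record: SequenceRecord | str,
                  params: TandemParams = TandemParams()) -> list[TandemArray]:
    """Detect tandem arrays in one sequence.

    Candidate periods are proposed where the sequence matches itself
    densely at a lag; each candidate window is verified by a wraparound
    local alignment against its phase consensus, extended maximally by the
    local alignment itself. Reported arrays have score >= 50 and copy
    number >= 1.8; periodic consensus motifs are reduced to their
    primitive period.
    """
    if isinstance(record, str):
        record = SequenceRecord(id="seq", residues=record)
    seq = record.residues
    n = len(seq)
    if n < 2 * params.min_period:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    accepted: list[TandemArray] = []
    seen: set[tuple[int, int, int]] = set()
    max_p = min(params.max_period, n // 2)
    for p in range(params.min_period, max_p + 1):
        for cs, ce in _candidate_regions(arr, p):
            s0 = max(0, cs - p - 10)
            e0 = min(n, ce + 2 * p + 10)
            if _covered(accepted, s0, e0, p):
                continue
            for arrp in _verify_window(record.id, arr, seq, s0, e0, p,
                                       params):
                key = (arrp.interval.start, arrp.interval.end,
                       arrp.period_size)
                if key not in seen:
                    seen.add(key)
                    accepted.append(arrp)
    accepted.sort(key=lambda a: (a.interval.start, a.interval.end,
                                 a.period_size))
    return accepted


def _verify_window(seq_id: str, arr: np.ndarray, seq: str, s0: int, e0: int,
                   period: int, params: TandemParams) -> list[TandemArray]:
    out: list[TandemArray] = []
    max_len = max(_MAX_DP_CELLS // period, 4 * period)
    chunk_starts = list(range(s0, e0, max_len - 3 * period))
    for c0 in chunk_starts:
        c1 = min(e0, c0 + max_len)
        window = arr[c0:c1]
        if len(window) < int(params.min_copies * period):
            continue
        consensus = _phase_consensus(window, period)
        res = _wraparound_local(window, consensus, params)
        if res is None:
            continue
        score, w_start, w_end, matches, columns, consumed = res
        copies = consumed / period
        if copies < params.min_copies:
            continue
        start, end = c0 + w_start, c0 + w_end
        motif = consensus.tobytes().decode()
        # rotate the consensus to the phase of the array start
        phase = (start - c0) % period
        motif = motif[phase:] + motif[:phase]
        d = primitive_period(motif)
        if d < params.min_period:
            continue  # mononucleotide arrays are out of scope
        if d < period:
            motif = motif[:d]
            copies = consumed / d
        span = seq[start:end]
        at = (span.count("A") + span.count("T")) / len(span)
        out.append(TandemArray(
            interval=GenomeInterval(seq_id, start, end),
            period_size=d,
            copy_number=round(copies, 1),
            consensus_motif=motif,
            percent_matches=matches / columns if columns else 0.0,
            score=float(score),
            at_fraction=at,
        ))
        if c1 >= e0:
            break
    return _merge_same_period(out)


def _merge_same_period(arrays: list[TandemArray]) -> list[TandemArray]:
    """Merge overlapping/abutting arrays of the same period (chunk seams)."""
    arrays = sorted(arrays, key=lambda a: (a.period_size, a.interval.start))
    out: list[TandemArray] = []
    for a in arrays:
        if (out and out[-1].period_size == a.period_size
                and out[-1].interval.seq_id == a.interval.seq_id
                and a.interval.start <= out[-1].interval.end + a.period_size):
            prev = out[-1]
            start = prev.interval.start
            end = max(prev.interval.end, a.interval.end)
            out[-1] = TandemArray(
                interval=GenomeInterval(a.interval.seq_id, start, end),
                period_size=a.period_size,
                copy_number=round((end - start) / a.period_size, 1),
                consensus_motif=prev.consensus_motif,
                percent_matches=min(prev.percent_matches, a.percent_matches),
                score=prev.score + a.score,
                at_fraction=(prev.at_fraction + a.at_fraction) / 2,
            )
        else:
            out.append(a)
    return out


def detect_tandem_set(seqs: SequenceSet,
                      params: TandemParams = TandemParams()
                      ) -> list[TandemArray]:
    """Run the detector over every record of a set."""
    arrays: list[TandemArray] = []
    for rec in seqs:
        arrays.extend(detect_tandem(rec, params))
    return arrays


# ---------------------------------------------------------------------------
# overlap resolution, classification, summaries


def resolve_tandem_overlaps(arrays: list[TandemArray],
                            max_overlap_frac: float = 0.10
                            ) -> list[TandemArray]:
    """Greedy overlap filtering by descending alignment score.

    Ties break toward the longer array, then the leftmost. An array
    overlapping an already accepted array by more than 10% of its own
    length is discarded. Output is sorted by position.
    """
    ordered = sorted(arrays, key=lambda a: (-a.score, -a.length,
                                            a.interval.seq_id,
                                            a.interval.start,
                                            a.period_size))
    accepted: list[TandemArray] = []
    for a in ordered:
        own = a.length
        if all(a.interval.overlap(b.interval) <= max_overlap_frac * own
               for b in accepted):
            accepted.append(a)
    accepted.sort(key=lambda a: (a.interval.seq_id, a.interval.start,
                                 a.interval.end))
    return accepted


SUB_BIN_ORDER = (
    [("micro", MICRO_SUB_BINS[p]) for p in range(2, 9)]
    + [("mini", f"{lo}-{hi}") for lo, hi in MINI_SUB_BINS]
    + [("sat", f"{lo}-{hi}") for lo, hi in SAT_SUB_BINS[:-1]]
    + [("sat", ">400")]
)


@dataclass
class TandemSummary:
    """Per-bin tandem statistics with class and grand totals.

    ``table`` rows are (class, sub_bin) plus ``Total`` rows per class and
    a ``Grand Total``; columns: total_loci, copy_number, variants,
    total_length, pct_of_set. Totals are sums of their bins (variants
    totals count distinct canonical motifs within the class/grand scope).
    """

    table: pd.DataFrame
    set_len: int

    def row(self, class_: str, sub_bin: str) -> pd.Series:
        return self.table.loc[(class_, sub_bin)]

    def class_total(self, class_: str) -> pd.Series:
        return self.table.loc[(class_, "Total")]

    @property
    def grand_total(self) -> pd.Series:
        return self.table.loc[("all", "Grand Total")]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def classify_and_summarize(arrays: list[TandemArray],
                           seqs: SequenceSet) -> TandemSummary:
    """Bin overlap-resolved arrays and summarize per bin.

    Variants are distinct canonical motifs per bin; percent of set uses
    the set's non-N length; copy numbers are summed at one decimal.
    """
    set_len = seqs.total_non_n
    rows = {}
    per_bin: dict[tuple[str, str], list[TandemArray]] = {
        key: [] for key in SUB_BIN_ORDER
    }
    for a in arrays:
        per_bin[classify_period(a.period_size)].append(a)

    def stats(items: list[TandemArray]) -> dict:
        motifs = {canonical_motif(a.consensus_motif) for a in items}
        total_len = sum(a.length for a in items)
        return {
            "total_loci": len(items),
            "copy_number": round(sum(a.copy_number for a in items), 1),
            "variants": len(motifs),
            "total_length": total_len,
            "pct_of_set": round(100.0 * total_len / set_len, 3)
            if set_len else 0.0,
        }

    for (class_, sub_bin), items in per_bin.items():
        rows[(class_, sub_bin)] = stats(items)
    for class_ in ("micro", "mini", "sat"):
        items = [a for (c, _), arrs in per_bin.items() if c == class_
                 for a in arrs]
        rows[(class_, "Total")] = stats(items)
    rows[("all", "Grand Total")] = stats(arrays)
    index = pd.MultiIndex.from_tuples(rows.keys(),
                                      names=["class", "sub_bin"])
    table = pd.DataFrame(list(rows.values()), index=index)
    return TandemSummary(table=table, set_len=set_len)


def microsat_density(arrays: list[TandemArray],
                     seqs: SequenceSet) -> dict[str, float]:
    """Microsatellite loci per Mbp of non-N sequence, per sub-bin."""
    mbp = seqs.total_non_n / 1e6
    out = {MICRO_SUB_BINS[p]: 0.0 for p in range(2, 9)}
    if mbp == 0:
        return out
    for a in arrays:
        class_, sub_bin = classify_period(a.period_size)
        if class_ == "micro":
            out[sub_bin] += 1
    return {k: v / mbp for k, v in out.items()}


def at_richness(arrays: list[TandemArray]) -> float:
    """Fraction of arrays whose genomic span is AT-rich (A%+T% > 60%)."""
    if not arrays:
        return 0.0
    return sum(1 for a in arrays if a.at_rich) / len(arrays)
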