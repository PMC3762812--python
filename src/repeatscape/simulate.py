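"""Synthetic genomes with planted repeat families and tandem arrays.

Generates multi-sequence sets with an i.i.d. background at a target GC,
plants diverged copies of LTR/TIR/LINE-like element families (per-copy
substitutions and indels, optional 5' truncation and nesting) and tandem
arrays, and emits an exact ground-truth table for parameter-recovery
testing. Everything is driven by one seeded generator, so a fixed seed
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import TRNA_3PRIME_18MER
from .seqio import (Annotation, GenomeInterval, SequenceRecord, SequenceSet,
                    revcomp, write_bed, write_fasta)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ORDERS = {"LTR", "TIR", "LINE-like", "LINE"}


@dataclass(frozen=True)
class FamilySpec:
    """One planted transposable-element family.

    ``sub_rate`` is the per-site substitution probability of each copy
    relative to the family master; ``indel_rate`` the per-site probability
    of opening an indel (geometric length, mean 3). ``nest_prob`` is the
    probability a copy is inserted inside a previously planted copy and
    ``truncation_prob`` the probability of a 5'-truncated (LINE-like
    degradation) copy.
    """

    name: str
    order: str = "LTR"
    element_length: int = 3000
    ltr_length: int | None = 300
    copy_number: int = 8
    sub_rate: float = 0.05
    indel_rate: float = 0.0
    nest_prob: float = 0.0
    truncation_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.order not in _ORDERS:
            raise ValueError(f"unknown order {self.order!r}")
        for rate in (self.sub_rate, self.indel_rate, self.nest_prob,
                     self.truncation_prob):
            if not 0 <= rate <= 0.5:
                raise ValueError("rates must be within [0, 0.5]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.order in ("LTR", "TIR"):
            if self.ltr_length is None:
                raise ValueError(f"{self.order} family needs ltr_length")
            if self.ltr_length >= self.element_length / 2:
                raise ValueError(
                    "ltr_length must be < element_length / 2"
                )


@dataclass(frozen=True)
class TandemSpec:
    """One planted tandem array: a motif repeated ``copies`` times with
    per-site substitution divergence within the array."""

    motif: str
    copies: float = 10.0
    sub_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 2 <= len(self.motif) <= 500:
            raise ValueError("motif length must be within [2, 500]")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over {A,C,G,T}")
        if self.copies < 1.8:
            raise ValueError("copies must be >= 1.8")
        if not 0 <= self.sub_rate <= 0.5:
            raise ValueError("sub_rate must be within [0, 0.5]")


@dataclass
class GenomeSpec:
    """Specification of a simulated sequence set."""

    n_sequences: int = 3
    length_distribution: tuple[int, int] | list[int] = (150_000, 250_000)
    gc: float = 0.38
    seed: int = 0
    families: list[FamilySpec] = field(default_factory=list)
    tandems: list[TandemSpec] = field(default_factory=list)


class GroundTruth:
    """Planted-feature table: one row per feature with exact coordinates,
    realized identity to the family master, and flags."""

    COLUMNS = ["seq_id", "start", "end", "strand", "kind", "name",
               "full_length", "nested", "identity"]

    def __init__(self, rows: list[dict] | None = None):
        self.rows = rows or []

    def add(self, **row) -> dict:
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        if not self.rows:
            return pd.DataFrame(columns=self.COLUMNS)
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def te_rows(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["kind"] == "TE"]

    def tandem_rows(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["kind"] == "tandem"]

    def total_bp(self, kind: str | None = None) -> int:
        df = self.to_frame()
        if kind is not None:
            df = df[df["kind"] == kind]
        return int((df["end"] - df["start"]).sum()) if len(df) else 0

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_dict("records"))

    def to_annotations(self) -> list[Annotation]:
        return [
            Annotation(
                interval=GenomeInterval(r["seq_id"], int(r["start"]),
                                        int(r["end"]), r["strand"]),
                category=f"{r['kind']}:{r['name']}",
                score=0.0,
            )
            for r in self.rows
        ]


def random_sequence(n: int, rng: np.random.Generator,
                    gc: float = 0.38) -> str:
    """i.i.d. sequence with P(G or C) = gc."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return BASES[idx].tobytes().decode()


def _random_purine_run(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(["A", "G"], size=n))


def build_master_element(spec: FamilySpec, rng: np.random.Generator,
                         gc: float = 0.38,
                         trna_3prime: str = TRNA_3PRIME_18MER) -> str:
    """The undiverged master sequence of a family.

    LTR order: identical direct terminal repeats, an 18 bp primer binding
    site (reverse complement of the tRNA 3' end) adjacent to the 5' LTR
    interior and a 13 bp polypurine tract adjacent to the 3' LTR interior.
    TIR order: reverse-complement terminal repeats. LINE-like: a poly-A
    3' tail.
    """
    n = spec.element_length
    if spec.order == "LTR":
        ltr_len = spec.ltr_length
        assert ltr_len is not None
        pbs = revcomp(trna_3prime)
        ppt = _random_purine_run(13, rng)
        inner = n - 2 * ltr_len - len(pbs) - len(ppt)
        if inner < 1:
            raise ValueError("element too short for its LTRs and signals")
        ltr = random_sequence(ltr_len, rng, gc)
        return ltr + pbs + random_sequence(inner, rng, gc) + ppt + ltr
    if spec.order == "TIR":
        tir_len = spec.ltr_length
        assert tir_len is not None
        tir = random_sequence(tir_len, rng, gc)
        mid = n - 2 * tir_len
        if mid < 1:
            raise ValueError("element too short for its inverted repeats")
        return tir + random_sequence(mid, rng, gc) + revcomp(tir)
    # LINE-like: poly-A tail of 12 A at the 3' end
    tail = 12
    if n <= tail:
        raise ValueError("element too short for a poly-A tail")
    return random_sequence(n - tail, rng, gc) + "A" * tail


def mutate_copy(master: str, sub_rate: float, indel_rate: float,
                rng: np.random.Generator) -> tuple[str, float]:
    """A diverged copy plus its realized identity from the edit script.

    Substitutions are independent per site to a uniformly chosen different
    base; indels open with ``indel_rate`` per site (geometric length, mean
    3, insertion or deletion with equal probability). Identity is matches
    over alignment columns of the implied edit alignment.
    """
    out: list[str] = []
    matches = 0
    columns = 0
    skip = 0
    for base in master:
        if indel_rate and rng.random() < indel_rate:
            glen = int(rng.geometric(1.0 / 3.0))
            if rng.random() < 0.5:
                ins = random_sequence(glen, rng, 0.5)
                out.append(ins)
                columns += glen
            else:
                skip += glen
        if skip > 0:
            skip -= 1
            columns += 1
            continue
        columns += 1
        if sub_rate and rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
        else:
            out.append(base)
            matches += 1
    return "".join(out), matches / columns if columns else 1.0


def make_tandem_array(spec: TandemSpec,
                      rng: np.random.Generator) -> tuple[str, float]:
    """The planted array sequence and its realized identity to a perfect
    array of the motif."""
    total = int(round(spec.copies * len(spec.motif)))
    perfect = (spec.motif * math.ceil(spec.copies + 1))[:total]
    arr = np.frombuffer(perfect.encode(), dtype=np.uint8).copy()
    if spec.sub_rate:
        hit = rng.random(total) < spec.sub_rate
        for i in np.flatnonzero(hit):
            cur = chr(arr[i])
            arr[i] = ord(rng.choice([b for b in "ACGT" if b != cur]))
        identity = 1.0 - hit.sum() / total
    else:
        identity = 1.0
    return arr.tobytes().decode(), identity


class _Placer:
    """Non-overlapping feature placement by background replacement."""

    MAX_FILL = 0.7
    MARGIN = 10

    def __init__(self, seqs: list[list[str]], rng: np.random.Generator):
        # each sequence is held as a mutable list of one string for speed
        self.seqs = seqs
        self.rng = rng
        self.planted: list[list[dict]] = [[] for _ in seqs]
        self.planted_bp = [0] * len(seqs)

    def _free(self, i: int) -> int:
        return int(self.MAX_FILL * len(self.seqs[i][0])) - self.planted_bp[i]

    def place(self, feature: str, truth_row: dict) -> dict:
        """Replace a background window with the feature; returns the row
        completed with seq index and coordinates."""
        flen = len(feature)
        candidates = [i for i in range(len(self.seqs))
                      if self._free(i) >= flen
                      and len(self.seqs[i][0]) > flen + 2 * self.MARGIN]
        if not candidates:
            raise ValueError("planted content exceeds genome capacity")
        weights = np.array([self._free(i) for i in candidates], dtype=float)
        order = list(self.rng.permutation(len(candidates)))
        order.sort(key=lambda j: -weights[j])
        for j in order:
            i = candidates[j]
            seq = self.seqs[i][0]
            for _ in range(500):
                pos = int(self.rng.integers(0, len(seq) - flen))
                lo, hi = pos - self.MARGIN, pos + flen + self.MARGIN
                if all(r["end"] <= lo or r["start"] >= hi
                       for r in self.planted[i]):
                    self.seqs[i][0] = seq[:pos] + feature + seq[pos + flen:]
                    truth_row.update(seq=i, start=pos, end=pos + flen)
                    self.planted[i].append(truth_row)
                    self.planted_bp[i] += flen
                    return truth_row
        raise ValueError("planted content exceeds genome capacity "
                         "(placement retries exhausted)")

    def nest(self, feature: str, host: dict, truth_row: dict) -> dict:
        """Insert the feature inside a host copy, lengthening the
        sequence; the host row keeps its (now wider) span."""
        i = host["seq"]
        flen = len(feature)
        pad = min(50, (host["end"] - host["start"]) // 4)
        pos = int(self.rng.integers(host["start"] + pad, host["end"] - pad))
        seq = self.seqs[i][0]
        self.seqs[i][0] = seq[:pos] + feature + seq[pos:]
        for row in self.planted[i]:
            if row["start"] >= pos:
                row["start"] += flen
                row["end"] += flen
            elif row["end"] > pos:
                row["end"] += flen
        host["nested"] = True
        truth_row.update(seq=i, start=pos, end=pos + flen)
        self.planted[i].append(truth_row)
        self.planted_bp[i] += flen
        return truth_row


def simulate(spec: GenomeSpec) -> tuple[SequenceSet, GroundTruth]:
    """Generate the sequence set and its exact ground truth."""
    seqs, truth, _masters = simulate_with_masters(spec)
    return seqs, truth


def simulate_with_masters(
    spec: GenomeSpec,
) -> tuple[SequenceSet, GroundTruth, dict[str, str]]:
    """Like :func:`simulate` but also returns the family master sequences."""
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.length_distribution, (tuple,)):
        lo, hi = spec.length_distribution
        lengths = [int(rng.integers(lo, hi + 1))
                   for _ in range(spec.n_sequences)]
    else:
        lengths = [int(x) for x in spec.length_distribution]
        if len(lengths) != spec.n_sequences:
            raise ValueError("length list does not match n_sequences")
    seqs = [[random_sequence(n, rng, spec.gc)] for n in lengths]
    placer = _Placer(seqs, rng)
    masters: dict[str, str] = {}
    for fam in spec.families:
        master = build_master_element(fam, rng, spec.gc)
        masters[fam.name] = master
        for _ in range(fam.copy_number):
            copy, identity = mutate_copy(master, fam.sub_rate,
                                         fam.indel_rate, rng)
            full = True
            if fam.truncation_prob and rng.random() < fam.truncation_prob:
                cut = int(len(copy) * rng.uniform(0.3, 0.7))
                copy = copy[cut:]
                full = False
            strand = "+" if rng.random() < 0.5 else "-"
            planted_seq = copy if strand == "+" else revcomp(copy)
            row = dict(kind="TE", name=fam.name, full_length=full,
                       nested=False, identity=round(identity, 4),
                       strand=strand)
            te_hosts = [r for rows in placer.planted for r in rows
                        if r["kind"] == "TE"
                        and r["end"] - r["start"] > len(planted_seq) // 2]
            if (fam.nest_prob and te_hosts
                    and rng.random() < fam.nest_prob):
                host = te_hosts[int(rng.integers(len(te_hosts)))]
                placer.nest(planted_seq, host, row)
            else:
                placer.place(planted_seq, row)
    for tandem in spec.tandems:
        arr, identity = make_tandem_array(tandem, rng)
        row = dict(kind="tandem", name=tandem.motif, full_length=True,
                   nested=False, identity=round(identity, 4), strand="+")
        placer.place(arr, row)
    records = [SequenceRecord(id=f"seq{i}", residues=s[0])
               for i, s in enumerate(seqs)]
    truth = GroundTruth()
    all_rows = [r for rows in placer.planted for r in rows]
    all_rows.sort(key=lambda r: (r["seq"], r["start"], r["end"]))
    for r in all_rows:
        truth.add(seq_id=f"seq{r.pop('seq')}", start=r["start"],
                  end=r["end"], strand=r["strand"], kind=r["kind"],
                  name=r["name"], full_length=r["full_length"],
                  nested=r["nested"], identity=r["identity"])
    return SequenceSet(records, label="simulated"), truth, masters


def write_outputs(seqs: SequenceSet, truth: GroundTruth,
                  outdir: str | Path) -> dict[str, Path]:
    """FASTA + truth TSV + truth BED under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "truth_tsv": outdir / "truth.tsv",
        "truth_bed": outdir / "truth.bed",
    }
    write_fasta(seqs, paths["fasta"])
    truth.to_tsv(paths["truth_tsv"])
    write_bed(truth.to_annotations(), paths["truth_bed"],
              lengths=seqs.lengths())
    return paths


def spec_from_config(path: str | Path) -> GenomeSpec:
    """Load a GenomeSpec from a YAML/JSON config file.

    Top-level keys mirror the GenomeSpec fields; ``families`` and
    ``tandems`` are lists of mappings with the FamilySpec/TandemSpec field
    names.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    families = [FamilySpec(**f) for f in cfg.get("families", [])]
    tandems = [TandemSpec(**t) for t in cfg.get("tandems", [])]
    length = cfg.get("length_distribution", (150_000, 250_000))
    if isinstance(length, (list, tuple)) and len(length) == 2 \
            and not cfg.get("length_is_list", False):
        length = (int(length[0]), int(length[1]))
    return GenomeSpec(
        n_sequences=int(cfg.get("n_sequences", 3)),
        length_distribution=length,
        gc=float(cfg.get("gc", 0.38)),
        seed=int(cfg.get("seed", 0)),
        families=families,
        tandems=tandems,
    )
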