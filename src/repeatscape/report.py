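"""Combined repeat-content accounting.

Merges the tandem and interspersed (homology + de novo) annotation layers
into one report: per-class coverage for filtered (full-length) and
unfiltered (partial + full-length) modes, tandem content before and after
subtracting overlap with interspersed elements, and total repetitive
content per mode. The homology and de novo interval sets are combined by
union before coverage is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import (Annotation, GenomeInterval, SequenceSet,
                    merged_coverage, subtract_intervals)
from .tandem import TandemArray

CLASS_ROWS = ("I", "II", "Other")


def _class_of(category: str) -> str:
    head = category.split("/", 1)[0]
    return head if head in ("I", "II") else "Other"


def tandem_annotations(arrays: list[TandemArray]) -> list[Annotation]:
    return [
        Annotation(interval=a.interval,
                   category=f"tandem/{a.consensus_motif}",
                   score=a.score,
                   attributes={"period": str(a.period_size),
                               "copies": f"{a.copy_number:.1f}"})
        for a in arrays
    ]


def subtract_overlap(
    tandem_anns: list[Annotation],
    interspersed_anns: list[Annotation],
    set_len: int,
) -> tuple[list[Annotation], int, float]:
    """Remove interspersed-covered bp from tandem annotations.

    Tandem intervals are trimmed/split against the union of interspersed
    intervals; returns the residual annotations, residual bp and residual
    percent of the set.
    """
    inter = [a.interval for a in interspersed_anns]
    residual: list[Annotation] = []
    for ann in tandem_anns:
        for piece in subtract_intervals([ann.interval], inter):
            residual.append(Annotation(interval=piece, category=ann.category,
                                       score=ann.score,
                                       attributes=dict(ann.attributes)))
    bp = merged_coverage([a.interval for a in residual])
    pct = 100.0 * bp / set_len if set_len else 0.0
    return residual, bp, pct


@dataclass
class ContentReport:
    """Class-level repetitive-content table plus tandem accounting.

    ``interspersed`` rows are Class I / Class II / Other plus a Total row
    (by summation); columns give bp and percent of set per mode. The
    invariant filtered <= unfiltered holds per category, and total
    repetitive content is the interspersed total plus the non-overlapping
    tandem content of the same mode.
    """

    interspersed: pd.DataFrame
    tandem_bp_raw: int
    tandem_pct_raw: float
    tandem_nonoverlap: dict[str, tuple[int, float]]
    set_len: int
    decimals: int = 2

    totals: dict[str, float] = field(default_factory=dict)

    def total_repetitive_pct(self, mode: str = "unfiltered") -> float:
        return self.totals[mode]

    def to_tsv(self, path: str | Path) -> None:
        self.interspersed.to_csv(path, sep="\t")


def content_report(
    seqs: SequenceSet,
    tandem_arrays: list[TandemArray],
    interspersed: dict[str, list[Annotation]],
    decimals: int = 2,
) -> ContentReport:
    """Combine stage outputs into the headline accounting.

    ``interspersed`` maps mode ("unfiltered", "filtered") to the combined
    homology + de novo annotation list for that mode (the caller
    concatenates the layers; coverage is computed on the interval union).
    """
    set_len = seqs.total_non_n
    lengths = seqs.lengths()
    for anns in interspersed.values():
        for a in anns:
            if a.interval.seq_id not in lengths:
                raise ValueError(
                    f"annotation on unknown sequence {a.interval.seq_id!r}"
                )
    modes = sorted(interspersed)
    rows: dict[str, dict[str, float]] = {c: {} for c in CLASS_ROWS}
    totals_bp: dict[str, int] = {}
    for mode, anns in interspersed.items():
        by_class: dict[str, list[GenomeInterval]] = {c: [] for c in CLASS_ROWS}
        for a in anns:
            by_class[_class_of(a.category)].append(a.interval)
        mode_total = 0
        for c in CLASS_ROWS:
            bp = merged_coverage(by_class[c])
            rows[c][f"{mode}_bp"] = bp
            rows[c][f"{mode}_pct"] = round(100.0 * bp / set_len, decimals) \
                if set_len else 0.0
            mode_total += bp
        totals_bp[mode] = mode_total
    table = pd.DataFrame.from_dict(rows, orient="index")
    total_row = {}
    for mode in modes:
        total_row[f"{mode}_bp"] = totals_bp[mode]
        total_row[f"{mode}_pct"] = round(
            100.0 * totals_bp[mode] / set_len, decimals) if set_len else 0.0
    table.loc["Total"] = pd.Series(total_row)

    t_anns = tandem_annotations(tandem_arrays)
    tandem_bp = merged_coverage([a.interval for a in t_anns])
    tandem_pct = 100.0 * tandem_bp / set_len if set_len else 0.0
    nonoverlap: dict[str, tuple[int, float]] = {}
    totals: dict[str, float] = {}
    for mode in modes:
        _res, bp, pct = subtract_overlap(t_anns, interspersed[mode], set_len)
        nonoverlap[mode] = (bp, pct)
        totals[mode] = round(
            (100.0 * totals_bp[mode] / set_len if set_len else 0.0) + pct,
            decimals,
        )
    return ContentReport(
        interspersed=table,
        tandem_bp_raw=tandem_bp,
        tandem_pct_raw=round(tandem_pct, decimals),
        tandem_nonoverlap=nonoverlap,
        set_len=set_len,
        decimals=decimals,
        totals=totals,
    )


def genome_fraction(seqs: SequenceSet, genome_size_bp: float) -> float:
    """Percent of an estimated genome size represented by the set's raw
    (N-included) length, two decimals."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    raw = sum(len(rec) for rec in seqs)
    return round(100.0 * raw / genome_size_bp, 2)
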