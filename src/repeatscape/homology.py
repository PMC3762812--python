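"""Homology-based interspersed repeat annotation.

Aligns genomic sequences against a classified repeat library, computes the
gap-adjusted identity (*sim*) of every hit, applies the modified 80-80-80
full-length standard (alignment span on the reference element > 80 bp, sim
>= 0.80, and coverage of >= 80% of the reference element), and accounts
coverage per family/superfamily/order/class in redundant (a region may be
annotated more than once) or non-redundant (the highest-scoring annotation
wins) modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import _blast
from .align import AlignmentHit, DEFAULT_SCORING, MIN_HIT_SCORE
from .library import RepeatLibrary
from .seqio import Annotation, GenomeInterval, SequenceSet, merge_intervals

__all__ = [
    "AlignmentHit", "FilterParams", "CoverageReport", "sim_metric",
    "local_align", "read_blast_m8", "full_length_filter", "nonredundant",
    "annotate_set", "gypsy_copia_ratio",
]

# re-exported: the aligner lives with the other pairwise primitives
from .align import local_align  # noqa: E402


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the modified 80-80-80 full-length standard.

    ``min_len`` is a strict lower bound on the hit's span on the reference
    (library) element in bp; ``min_sim`` and ``min_subject_cov`` are
    inclusive lower bounds on the sim metric and on the fraction of the
    reference element covered.
    """

    min_len: int = 80
    min_sim: float = 0.80
    min_subject_cov: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.min_sim <= 1 and 0 < self.min_subject_cov <= 1):
            raise ValueError("fraction thresholds must be in (0, 1]")


def sim_metric(hit: AlignmentHit) -> float:
    """Gap-adjusted identity: match_count / (alignment_length -
    query_gap_length - subject_gap_length + gap_count).

    For a gap-free alignment all gap terms vanish and the metric reduces to
    fraction identity. The value is stored on the hit.
    """
    denom = (hit.alignment_length - hit.query_gap_length
             - hit.subject_gap_length + hit.gap_count)
    if denom <= 0:
        raise ValueError(f"non-positive sim denominator ({denom})")
    hit.sim = hit.match_count / denom
    return hit.sim


def read_blast_m8(path: str | Path, library: RepeatLibrary | None = None,
                  min_score: float = 0.0) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular output into alignment hits.

    Hits are rescored in the internal scoring units and carry the sim
    metric. If a library is given, unknown subjects are an error.
    """
    hits = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            hit = _blast.parse_m8_line(line, i)
            if library is not None and hit.subject_name not in library:
                raise KeyError(f"subject {hit.subject_name!r} not in library")
            sim_metric(hit)
            if hit.score >= min_score:
                hits.append(hit)
    return hits


def full_length_filter(
    hits: list[AlignmentHit],
    library: RepeatLibrary,
    params: FilterParams = FilterParams(),
) -> list[AlignmentHit]:
    """Keep hits that satisfy the modified 80-80-80 standard."""
    kept = []
    for hit in hits:
        subject_len = len(library[hit.subject_name])
        if hit.sim is None:
            sim_metric(hit)
        if (hit.subject_span > params.min_len
                and hit.sim >= params.min_sim
                and hit.subject_span / subject_len >= params.min_subject_cov):
            kept.append(hit)
    return kept


def _overlap(a: AlignmentHit, b: AlignmentHit) -> int:
    if a.query_id != b.query_id:
        return 0
    return max(0, min(a.qend, b.qend) - max(a.qstart, b.qstart))


def nonredundant(hits: list[AlignmentHit],
                 max_overlap_frac: float = 0.50) -> list[AlignmentHit]:
    """Greedy non-redundant selection by descending alignment score.

    Ties break toward the longer query span, then the lexicographically
    smaller subject name. A hit whose query span overlaps an already
    accepted hit by more than ``max_overlap_frac`` of its own span is
    discarded. Output is sorted by genomic position.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, -h.query_span,
                                          h.subject_name, h.query_id,
                                          h.qstart, h.strand))
    accepted: list[AlignmentHit] = []
    for hit in ordered:
        own = hit.query_span
        if all(_overlap(hit, a) <= max_overlap_frac * own for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: (h.query_id, h.qstart, h.qend))
    return accepted


@dataclass
class CoverageReport:
    """Merged-bp and percent-of-set coverage per classification level.

    ``paths`` maps (class, order, superfamily, family) to merged bp over
    that category's hits; aggregates at coarser levels are sums over the
    finest-level rows, so class totals equal the sum over their orders by
    construction.
    """

    paths: dict[tuple[str, str, str, str], int]
    set_len: int
    mode: str = "redundant"
    filtered: bool = False

    def _agg(self, depth: int) -> dict[tuple[str, ...], int]:
        out: dict[tuple[str, ...], int] = {}
        for path, bp in self.paths.items():
            key = path[:depth]
            out[key] = out.get(key, 0) + bp
        return out

    def by_class(self) -> dict[str, int]:
        return {k[0]: v for k, v in self._agg(1).items()}

    def by_order(self) -> dict[tuple[str, str], int]:
        return self._agg(2)  # type: ignore[return-value]

    def by_superfamily(self) -> dict[tuple[str, str, str], int]:
        return self._agg(3)  # type: ignore[return-value]

    def by_family(self) -> dict[tuple[str, str, str, str], int]:
        return dict(self.paths)

    @property
    def total_bp(self) -> int:
        return sum(self.paths.values())

    def pct(self, bp: int) -> float:
        return 100.0 * bp / self.set_len if self.set_len else 0.0

    @property
    def total_pct(self) -> float:
        return self.pct(self.total_bp)

    def superfamily_pct(self, name: str) -> float:
        bp = sum(v for k, v in self._agg(3).items() if k[2] == name)
        return self.pct(bp)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-category table (one row per level x category)."""
        rows = []
        levels = ["class", "order", "superfamily", "family"]
        for depth, level in enumerate(levels, start=1):
            for key, bp in sorted(self._agg(depth).items()):
                rows.append({
                    "level": level, "category": "/".join(key),
                    "bp": bp, "pct_of_set": round(self.pct(bp), 4),
                })
        rows.append({"level": "total", "category": "Total",
                     "bp": self.total_bp,
                     "pct_of_set": round(self.total_pct, 4)})
        return pd.DataFrame(rows, columns=["level", "category", "bp",
                                           "pct_of_set"])


def hits_to_annotations(hits: list[AlignmentHit],
                        library: RepeatLibrary) -> list[Annotation]:
    """Annotation per hit; the category is the classification path."""
    anns = []
    for hit in hits:
        cls = library[hit.subject_name].classification
        anns.append(Annotation(
            interval=GenomeInterval(hit.query_id, hit.qstart, hit.qend,
                                    hit.strand),
            category=cls.header_tag(),
            score=max(hit.score, 0.0),
            attributes={
                "subject": hit.subject_name,
                "sim": f"{hit.sim:.4f}" if hit.sim is not None else "NA",
            },
        ))
    return anns


def annotate_set(
    seqs: SequenceSet,
    library: RepeatLibrary,
    params: FilterParams = FilterParams(),
    mode: str = "redundant",
    filtered: bool = False,
    engine: str = "auto",
    min_score: float = MIN_HIT_SCORE,
) -> tuple[list[Annotation], CoverageReport]:
    """Annotate a sequence set against a repeat library.

    ``mode`` is ``redundant`` or ``nonredundant``; ``filtered`` applies the
    80-80-80 full-length standard first. Coverage is the merged union of
    hit spans per finest-level category, with percentages over the set's
    non-N length.
    """
    if len(library) == 0:
        raise ValueError("empty repeat library")
    if mode not in ("redundant", "nonredundant"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = _blast.search(
        {rec.id: rec.residues for rec in seqs}, library.sequences(),
        min_score=min_score, engine=engine, scoring=DEFAULT_SCORING,
    )
    for hit in hits:
        sim_metric(hit)
    if filtered:
        hits = full_length_filter(hits, library, params)
    if mode == "nonredundant":
        hits = nonredundant(hits)
    by_path: dict[tuple[str, str, str, str], list[GenomeInterval]] = {}
    for hit in hits:
        path = library[hit.subject_name].classification.path
        by_path.setdefault(path, []).append(
            GenomeInterval(hit.query_id, hit.qstart, hit.qend)
        )
    paths = {
        path: sum(e - s for spans in merge_intervals(ivs).values()
                  for s, e in spans)
        for path, ivs in by_path.items()
    }
    report = CoverageReport(paths=paths, set_len=seqs.total_non_n,
                            mode=mode, filtered=filtered)
    return hits_to_annotations(hits, library), report


def gypsy_copia_ratio(report: CoverageReport) -> float | None:
    """Gypsy-to-Copia coverage ratio, one decimal; None when undefined."""
    gypsy = report.superfamily_pct("Gypsy")
    copia = report.superfamily_pct("Copia")
    if copia == 0:
        return None
    return round(gypsy / copia, 1)
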