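"""Sequence and interval foundation.

FASTA I/O with alphabet normalization, per-set summary statistics (non-N
length, GC, N50), interval arithmetic on 0-based half-open coordinates, and
annotation export to GFF3/BED.

All in-memory coordinates are 0-based half-open; 1-based inclusive
conventions appear only at format boundaries (GFF3, tandem-finder ``.dat``,
BLAST tabular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named genomic sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def non_n_length(self) -> int:
        return len(self.residues) - self.residues.count("N")


@dataclass
class SequenceSet:
    """Ordered collection of uniquely named sequences."""

    records: list[SequenceRecord]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
        self._index = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def lengths(self) -> dict[str, int]:
        return {rec.id: len(rec) for rec in self.records}

    @property
    def total_non_n(self) -> int:
        return sum(rec.non_n_length for rec in self.records)


@dataclass(frozen=True)
class SetSummary:
    """Set-level statistics; lengths exclude unresolved (N) residues."""

    count: int
    total_len: int
    mean_len: int
    median_len: int
    n50: int
    shortest: int
    longest: int
    gc: float


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Overlap length in bp; 0 for different sequences."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Annotation:
    """A categorized, scored interval with free-form attributes."""

    interval: GenomeInterval
    category: str
    score: float = 0.0
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("annotation score must be >= 0")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, label: str = "") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Residues are uppercased; any character outside {A,C,G,T,N} is mapped to
    N (count logged). An empty file or a duplicate id is an error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        cleaned = "".join(c if c in ALPHABET else "N" for c in residues)
        n_mapped += sum(1 for a, b in zip(residues, cleaned) if a != b)
        records.append(SequenceRecord(id=rec.id, residues=cleaned))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_mapped:
        logger.warning("mapped %d non-ACGTN characters to N in %s", n_mapped, path)
    return SequenceSet(records=records, label=label or path.stem)


def write_fasta(seqs: SequenceSet | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    """Write sequences to FASTA (fixed line width, deterministic)."""
    if isinstance(seqs, SequenceSet):
        items = [(rec.id, rec.residues) for rec in seqs]
    else:
        items = list(seqs.items())
    bio = [_BioSeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Set statistics


def gc_content(record: SequenceRecord | str) -> float:
    """(G+C) / (A+C+G+T) of one sequence; N residues are excluded.

    Raises on an all-N sequence (the denominator would be zero).
    """
    residues = record.residues if isinstance(record, SequenceRecord) else record
    denom = len(residues) - residues.count("N")
    if denom == 0:
        raise ValueError("gc_content undefined for an all-N sequence")
    return (residues.count("G") + residues.count("C")) / denom


def n50(lengths: Iterable[int]) -> int:
    """N50: largest L with cumulative length of sequences >= L covering
    at least half of the total."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    running = 0
    for length in ls:
        running += length
        if 2 * running >= total:
            return length
    return 0


def summarize_set(seqs: SequenceSet) -> SetSummary:
    """Summary statistics of a set; all lengths exclude N residues.

    Mean length is truncated toward zero (integer division of totals).
    """
    if len(seqs) == 0:
        raise ValueError("cannot summarize an empty sequence set")
    lengths = [rec.non_n_length for rec in seqs.records]
    total = sum(lengths)
    ls = sorted(lengths)
    mid = len(ls) // 2
    median = ls[mid] if len(ls) % 2 == 1 else (ls[mid - 1] + ls[mid]) // 2
    gc_num = sum(rec.residues.count("G") + rec.residues.count("C")
                 for rec in seqs.records)
    return SetSummary(
        count=len(seqs),
        total_len=total,
        mean_len=int(total / len(seqs)),
        median_len=median,
        n50=n50(lengths),
        shortest=min(lengths),
        longest=max(lengths),
        gc=gc_num / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# Interval arithmetic


def _check_bounds(intervals: Iterable[GenomeInterval],
                  lengths: Mapping[str, int] | None) -> None:
    if lengths is None:
        return
    for iv in intervals:
        if iv.seq_id not in lengths:
            raise ValueError(f"unknown sequence id {iv.seq_id!r}")
        if iv.end > lengths[iv.seq_id]:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) out of bounds on "
                f"{iv.seq_id} (length {lengths[iv.seq_id]})"
            )


def merge_intervals(
    intervals: Iterable[GenomeInterval],
) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per sequence, as sorted disjoint (start, end)."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for seq_id, spans in by_seq.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[seq_id] = out
    return merged


def merged_coverage(intervals: Iterable[GenomeInterval],
                    lengths: Mapping[str, int] | None = None) -> int:
    """Total bp covered by the union of the intervals across sequences."""
    intervals = list(intervals)
    _check_bounds(intervals, lengths)
    merged = merge_intervals(intervals)
    return sum(e - s for spans in merged.values() for s, e in spans)


def subtract_intervals(
    minuend: Iterable[GenomeInterval],
    subtrahend: Iterable[GenomeInterval],
) -> list[GenomeInterval]:
    """Parts of ``minuend`` intervals not covered by ``subtrahend``.

    Intervals are trimmed or split as needed; strand is preserved.
    """
    cover = merge_intervals(subtrahend)
    out: list[GenomeInterval] = []
    for iv in minuend:
        pieces = [(iv.start, iv.end)]
        for cs, ce in cover.get(iv.seq_id, []):
            nxt: list[tuple[int, int]] = []
            for s, e in pieces:
                if ce <= s or cs >= e:
                    nxt.append((s, e))
                    continue
                if s < cs:
                    nxt.append((s, cs))
                if ce < e:
                    nxt.append((ce, e))
            pieces = nxt
            if not pieces:
                break
        out.extend(
            GenomeInterval(iv.seq_id, s, e, iv.strand) for s, e in pieces
        )
    return out


# ---------------------------------------------------------------------------
# Annotation export / import


def write_gff3(annotations: Iterable[Annotation], path: str | Path,
               lengths: Mapping[str, int] | None = None,
               source: str = "repeatscape") -> None:
    """Write annotations as GFF3 (1-based inclusive coordinates)."""
    annotations = list(annotations)
    _check_bounds((a.interval for a in annotations), lengths)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ann in enumerate(annotations):
            iv = ann.interval
            attrs = {"ID": f"ann{i}", **ann.attributes}
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join([
                    iv.seq_id, source, ann.category or "region",
                    str(iv.start + 1), str(iv.end),
                    f"{ann.score:g}", iv.strand, ".", attr_s,
                ]) + "\n"
            )


def write_bed(annotations: Iterable[Annotation], path: str | Path,
              lengths: Mapping[str, int] | None = None) -> None:
    """Write annotations as BED6 (0-based half-open)."""
    annotations = list(annotations)
    _check_bounds((a.interval for a in annotations), lengths)
    with open(path, "w") as fh:
        for ann in annotations:
            iv = ann.interval
            fh.write(
                "\t".join([
                    iv.seq_id, str(iv.start), str(iv.end),
                    ann.category.replace(" ", "_") or ".",
                    f"{ann.score:g}", iv.strand,
                ]) + "\n"
            )


def read_gff3(path: str | Path) -> list[Annotation]:
    """Read a GFF3 file written by :func:`write_gff3` back to annotations."""
    out: list[Annotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            attrs.pop("ID", None)
            out.append(Annotation(
                interval=GenomeInterval(f[0], int(f[3]) - 1, int(f[4]),
                                        f[6] if f[6] in "+-" else "."),
                category=f[2],
                score=float(f[5]) if f[5] != "." else 0.0,
                attributes=attrs,
            ))
    return out


def read_bed(path: str | Path) -> list[Annotation]:
    """Read a BED6 file back to annotations."""
    out: list[Annotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(Annotation(
                interval=GenomeInterval(f[0], int(f[1]), int(f[2]), strand),
                category=f[3] if len(f) > 3 else "",
                score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
            ))
    return out
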