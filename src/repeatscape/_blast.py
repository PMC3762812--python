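"""blastn-backed homology search engine.

Shells out to NCBI ``makeblastdb``/``blastn`` (when on PATH) with the
Censor normal-mode scoring (reward 3, penalty -4, gap open 5, extend 2,
word size 10, no low-complexity filtering) and ingests the 12-column
tabular output. Hits are rescored in the internal scoring units so that
downstream score thresholds do not depend on the engine.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

from .align import (AlignmentHit, AlignmentScoring, DEFAULT_SCORING,
                    internal_score, local_align)


@lru_cache(maxsize=1)
def blast_available() -> bool:
    return (shutil.which("blastn") is not None
            and shutil.which("makeblastdb") is not None)


def parse_m8_line(line: str, lineno: int = 0) -> AlignmentHit:
    """One 12-column BLAST tabular row -> AlignmentHit.

    Per-side gap residues are reconstructed as alignment columns minus each
    aligned span; match_count is rounded from the identity percentage;
    ``gapopen`` is taken as the number of gap openings. A subject start
    greater than the subject end encodes a minus-strand hit.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        raise ValueError(
            f"line {lineno}: expected 12 tab-separated columns, "
            f"got {len(fields)}"
        )
    (qid, sid, pident, length, mismatch, gapopen,
     qstart, qend, sstart, send, _evalue, _bitscore) = fields
    length = int(length)
    qstart, qend = int(qstart), int(qend)
    sstart, send = int(sstart), int(send)
    strand = "+" if sstart <= send else "-"
    s_lo, s_hi = min(sstart, send), max(sstart, send)
    match = round(float(pident) * length / 100.0)
    qgap = length - (qend - qstart + 1)
    sgap = length - (s_hi - s_lo + 1)
    n_open = int(gapopen)
    score = internal_score(match, int(mismatch), qgap + sgap, n_open)
    return AlignmentHit(
        query_id=qid, qstart=qstart - 1, qend=qend,
        subject_name=sid, sstart=s_lo - 1, send=s_hi, strand=strand,
        match_count=match, alignment_length=length,
        query_gap_length=qgap, subject_gap_length=sgap,
        gap_count=n_open, score=score,
    )


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def blastn_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_score: float = 50.0,
    evalue: float = 2e-5,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[AlignmentHit]:
    """All queries vs a database of subjects via blastn; sorted, rescored."""
    if not queries or not subjects:
        return []
    with tempfile.TemporaryDirectory(prefix="repeatscape_blast_") as tmp:
        tmpdir = Path(tmp)
        qpath, spath = tmpdir / "query.fa", tmpdir / "subject.fa"
        _write_fasta(queries, qpath)
        _write_fasta(subjects, spath)
        subprocess.run(
            ["makeblastdb", "-in", str(spath), "-dbtype", "nucl",
             "-out", str(tmpdir / "db"), "-logfile", str(tmpdir / "db.log")],
            check=True,
        )
        proc = subprocess.run(
            ["blastn", "-task", "blastn",
             "-query", str(qpath), "-db", str(tmpdir / "db"),
             "-reward", "3", "-penalty", "-4",
             "-gapopen", "5", "-gapextend", "2",
             "-word_size", "10", "-dust", "no", "-soft_masking", "false",
             "-evalue", str(evalue), "-num_threads", "1",
             "-outfmt", "6"],
            check=True, capture_output=True, text=True,
        )
    hits = []
    for i, line in enumerate(proc.stdout.splitlines(), start=1):
        if not line.strip():
            continue
        hit = parse_m8_line(line, i)
        if hit.score >= min_score:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.query_id, h.qstart,
                             h.subject_name, h.sstart, h.strand))
    return hits


def search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_score: float = 50.0,
    engine: str = "auto",
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[AlignmentHit]:
    """Homology search of every query against every subject.

    ``engine`` is ``blast`` (requires the NCBI binaries), ``internal``
    (pure-Python Smith-Waterman path) or ``auto`` (blast when available).
    Both engines emit hits under the same contract.
    """
    if engine == "auto":
        engine = "blast" if blast_available() else "internal"
    if engine == "blast":
        return blastn_search(queries, subjects, min_score, scoring=scoring)
    if engine != "internal":
        raise ValueError(f"unknown search engine {engine!r}")
    hits: list[AlignmentHit] = []
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            hits.extend(local_align(qseq, sseq, scoring, min_score,
                                    query_id=qid, subject_name=sid))
    hits.sort(key=lambda h: (-h.score, h.query_id, h.qstart,
                             h.subject_name, h.sstart, h.strand))
    return hits


def drop_self_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Remove identity-diagonal hits of a sequence set against itself."""
    return [
        h for h in hits
        if not (h.query_id == h.subject_name and h.strand == "+"
                and h.qstart == h.sstart and h.qend == h.send)
    ]
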