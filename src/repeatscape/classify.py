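"""Hierarchical classification of repeat elements.

Assigns Class/Order/Superfamily/family labels by a three-route precedence:

1. nucleotide homology — a library hit passing the 80-80-80 full-length
   standard inherits the library entry's full classification;
2. translated homology — a protein-level local alignment between extracted
   ORFs and library-entry ORFs (identity >= 0.35 over >= 100 aa) assigns
   the superfamily (and implied order/class) but never a family;
3. structural features — a direct long-terminal-repeat pair implies
   (Class I, LTR); an inverted pair implies (Class II, TIR); a poly-A tail
   with an ORF and no terminal repeats implies (Class I, LINE).

Also provides the structural detectors themselves: LTR/TIR pair discovery
on element termini, polypurine-tract (PPT) and primer-binding-site (PBS)
localization, and six-frame ORF extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .align import alignment_counts, hit_identity, local_align
from .homology import FilterParams, full_length_filter, sim_metric
from .library import (Classification, RepeatLibrary, UNKNOWN, order_to_class)
from .seqio import revcomp

# Synthetic stand-in for a host tRNA database: one 18-mer 3' end with the
# canonical T-loop motif and CCA terminus. The primer binding site of an
# LTR element is complementary to a tRNA 3' end.
TRNA_3PRIME_18MER = "GGGTTCGATTCCCGGCCA"


@dataclass(frozen=True)
class LtrPairParams:
    window: int = 2500          # bp examined at each terminus (cap)
    min_repeat_len: int = 100   # bp of the terminal repeat
    min_identity: float = 0.80  # matches / alignment columns
    min_element_len: int = 400


@dataclass(frozen=True)
class LtrPair:
    """A pair of terminal repeats in full-element coordinates."""

    left: tuple[int, int]
    right: tuple[int, int]
    identity: float
    orientation: str  # "direct" (LTR) or "inverted" (TIR)


@dataclass(frozen=True)
class Orf:
    """An open reading frame from a six-frame scan.

    ``frame`` is 0..2 on the forward strand, 3..5 on the reverse
    complement; ``start``/``end`` are 0-based half-open on the forward
    strand.
    """

    frame: int
    start: int
    end: int
    protein: str


@dataclass
class StructuralFeatures:
    ltr_pair: LtrPair | None = None
    pbs: tuple[int, int] | None = None
    ppt: tuple[int, int] | None = None
    tail: tuple[int, int] | None = None
    orfs: list[Orf] = field(default_factory=list)


def detect_ltr_pair(seq: str,
                    params: LtrPairParams = LtrPairParams()) -> LtrPair | None:
    """Find a direct (LTR) or inverted (TIR) terminal-repeat pair.

    The first W and last W bp (W = min(2500, len/3)) are locally aligned in
    both orientations; a repeat of >= 100 bp at >= 80% identity is
    accepted, preferring the higher-scoring orientation.
    """
    n = len(seq)
    if n < params.min_element_len:
        return None
    w = min(params.window, n // 3)
    head, tail = seq[:w], seq[-w:]
    offset = n - w
    best: LtrPair | None = None
    best_score = 0.0
    for orientation, subject in (("direct", tail), ("inverted", revcomp(tail))):
        hits = local_align(head, subject, both_strands=False,
                           min_score=params.min_repeat_len)
        for hit in hits:
            ident = hit_identity(hit)
            span = min(hit.query_span, hit.subject_span)
            if span < params.min_repeat_len or ident < params.min_identity:
                continue
            if hit.score <= best_score:
                continue
            if orientation == "direct":
                right = (offset + hit.sstart, offset + hit.send)
            else:
                # subject was the reverse complement of the terminal window
                right = (offset + (w - hit.send), offset + (w - hit.sstart))
            left = (hit.qstart, hit.qend)
            if right[0] < left[1]:  # the two repeats must not overlap
                continue
            best = LtrPair(left=left, right=right, identity=ident,
                           orientation=orientation)
            best_score = hit.score
    return best


def detect_ppt(seq: str, ltr_pair: LtrPair,
               window: int = 30, min_len: int = 10,
               min_purine: float = 0.90) -> tuple[int, int] | None:
    """Longest >= 10 bp window with >= 90% purines just inside the 3' LTR.

    The polypurine tract sits within 30 bp interior of the 3' LTR on the
    element strand (equivalently pyrimidines on the opposite strand).
    """
    lo = max(ltr_pair.left[1], ltr_pair.right[0] - window)
    hi = ltr_pair.right[0]
    region = seq[lo:hi]
    is_pur = [c in "AG" for c in region]
    for size in range(len(region), min_len - 1, -1):
        for start in range(0, len(region) - size + 1):
            if sum(is_pur[start:start + size]) >= min_purine * size:
                return (lo + start, lo + start + size)
    return None


def detect_pbs(seq: str, ltr_pair: LtrPair,
               trna_3prime: str = TRNA_3PRIME_18MER,
               window: int = 30, min_len: int = 11,
               max_mismatch: int = 1) -> tuple[int, int] | None:
    """Primer binding site adjacent to either LTR interior.

    Searches 30 bp inside each LTR for a >= 11 bp stretch matching the
    reverse complement of the tRNA 3' end with at most one mismatch;
    returns the best (longest, then fewest mismatches) site.
    """
    pbs_motif = revcomp(trna_3prime)
    regions = [
        (ltr_pair.left[1], min(ltr_pair.left[1] + window, ltr_pair.right[0])),
        (max(ltr_pair.right[0] - window, ltr_pair.left[1]), ltr_pair.right[0]),
    ]
    best: tuple[int, int, int, int] | None = None  # (-len, mm, start, end)
    for lo, hi in regions:
        region = seq[lo:hi]
        for k in range(len(pbs_motif), min_len - 1, -1):
            for m0 in range(0, len(pbs_motif) - k + 1):
                word = pbs_motif[m0:m0 + k]
                for start in range(0, len(region) - k + 1):
                    mm = sum(1 for a, b in zip(word, region[start:start + k])
                             if a != b)
                    if mm <= max_mismatch:
                        cand = (-k, mm, lo + start, lo + start + k)
                        if best is None or cand < best:
                            best = cand
    if best is None:
        return None
    return (best[2], best[3])


def detect_polya_tail(seq: str, min_a: int = 10,
                      window: int = 20) -> tuple[int, int] | None:
    """A run of >= 10 A within the last ``window`` bp (LINE-like 3' tail)."""
    tail_start = max(0, len(seq) - window)
    run = 0
    best: tuple[int, int] | None = None
    for i in range(tail_start, len(seq)):
        if seq[i] == "A":
            run += 1
            if run >= min_a:
                best = (i - run + 1, i + 1)
        else:
            run = 0
    return best


def extract_orfs(seq: str, min_aa: int = 100) -> list[Orf]:
    """Six-frame ORF scan with the standard genetic code.

    An ORF is a maximal stop-free codon run of at least ``min_aa`` amino
    acids; it may begin at the frame start (findorfs-style recovery).
    """
    orfs: list[Orf] = []
    n = len(seq)
    for strand, s in ((0, seq), (3, revcomp(seq))):
        for off in range(3):
            usable = (len(s) - off) // 3 * 3
            if usable < 3:
                continue
            prot = str(Seq(s[off:off + usable]).translate())
            pos = 0
            for segment in prot.split("*"):
                if len(segment) >= min_aa:
                    aa_start, aa_end = pos, pos + len(segment)
                    nt_start = off + 3 * aa_start
                    nt_end = off + 3 * aa_end
                    if strand == 0:
                        start, end = nt_start, nt_end
                    else:
                        start, end = n - nt_end, n - nt_start
                    orfs.append(Orf(frame=strand + off, start=start,
                                    end=end, protein=segment))
                pos += len(segment) + 1
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def _protein_aligner():
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def best_protein_match(
    query_orfs: list[Orf],
    library: RepeatLibrary,
    min_identity: float = 0.35,
    min_aa: int = 100,
) -> tuple[str, float, int] | None:
    """Best translated match of query ORFs to library-entry ORFs.

    Returns (library entry name, identity, aligned aa) for the best-scoring
    qualifying alignment, or None. Only library entries with a known
    superfamily are informative and considered.
    """
    aligner = _protein_aligner()
    best: tuple[float, str, float, int] | None = None
    for entry in library:
        if entry.classification.superfamily in (UNKNOWN, ""):
            continue
        for sorf in extract_orfs(entry.sequence, min_aa=min_aa):
            for qorf in query_orfs:
                try:
                    alns = aligner.align(qorf.protein, sorf.protein)
                except Exception:
                    continue
                if len(alns) == 0:
                    continue
                aln = alns[0]
                match, cols, _qg, _sg, _go = alignment_counts(
                    aln, qorf.protein, sorf.protein)
                if cols >= min_aa and match / cols >= min_identity:
                    cand = (float(aln.score), entry.name, match / cols, cols)
                    if best is None or cand[0] > best[0]:
                        best = cand
    if best is None:
        return None
    return best[1], best[2], best[3]


def structural_features(seq: str,
                        trna_3prime: str = TRNA_3PRIME_18MER,
                        min_aa: int = 100) -> StructuralFeatures:
    """All structural detectors on one element sequence."""
    feats = StructuralFeatures()
    feats.ltr_pair = detect_ltr_pair(seq)
    if feats.ltr_pair is not None and feats.ltr_pair.orientation == "direct":
        feats.ppt = detect_ppt(seq, feats.ltr_pair)
        feats.pbs = detect_pbs(seq, feats.ltr_pair, trna_3prime)
    feats.tail = detect_polya_tail(seq)
    feats.orfs = extract_orfs(seq, min_aa=min_aa)
    return feats


def classify_repeat(
    seq: str,
    library: RepeatLibrary | None,
    features: StructuralFeatures | None = None,
    params: FilterParams = FilterParams(),
    trna_3prime: str = TRNA_3PRIME_18MER,
) -> Classification:
    """Classify one repeat sequence by the three-route precedence.

    Nucleotide evidence assigns down to the family; protein evidence down
    to the superfamily; structural evidence down to the order. An empty
    library with no features yields an all-unknown classification.
    """
    # 1. nucleotide homology
    if library is not None and len(library) > 0:
        hits = []
        for entry in library:
            for hit in local_align(seq, entry.sequence,
                                   subject_name=entry.name):
                sim_metric(hit)
                hits.append(hit)
        passing = full_length_filter(hits, library, params)
        if passing:
            best = max(passing, key=lambda h: h.score)
            entry = library[best.subject_name]
            cls = entry.classification
            return Classification(
                class_=cls.class_, order=cls.order,
                superfamily=cls.superfamily,
                family=cls.family or entry.name,
                evidence="nucleotide",
            )
    if features is None:
        features = structural_features(seq, trna_3prime)
    # 2. translated (protein) homology: superfamily only
    if library is not None and len(library) > 0 and features.orfs:
        match = best_protein_match(features.orfs, library)
        if match is not None:
            entry = library[match[0]]
            sup = entry.classification.superfamily
            order = entry.classification.order
            return Classification(
                class_=order_to_class(order), order=order,
                superfamily=sup, family=None, evidence="protein",
            )
    # 3. structural features: order only
    pair = features.ltr_pair
    if pair is not None:
        if pair.orientation == "direct":
            return Classification(class_="I", order="LTR",
                                  evidence="structural")
        return Classification(class_="II", order="TIR",
                              evidence="structural")
    if features.tail is not None and features.orfs:
        return Classification(class_="I", order="LINE",
                              evidence="structural")
    return Classification()
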