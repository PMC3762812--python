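"""De novo repeat family discovery, clustering and coverage accounting.

The pipeline mirrors a seed-and-remap strategy: repetitive *seeds* are
discovered by all-vs-all self-alignment of the sequence set (plus a
structural pass for LTR-bounded spans), the seeds are used as a library to
re-map full-length instances back onto the reference (non-redundant search
plus the 80-80-80 full-length standard), the instances are clustered
greedily at 80% global identity into subfamilies, each cluster gets a
majority consensus, and clusters are merged into families by all-vs-all
alignment of their consensi (an edge when the hit satisfies the 80-80-80
standard with the shorter consensus as the reference; families are the
connected components). Family coverage sums the base pairs of all
full-length member sequences across the family's clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import _blast
from .align import global_identity, star_consensus
from .classify import detect_ltr_pair
from .homology import FilterParams, full_length_filter, nonredundant, sim_metric
from .library import Classification, RepeatLibrary, RepeatLibraryEntry
from .seqio import Annotation, GenomeInterval, SequenceSet, revcomp


@dataclass(frozen=True)
class SeedParams:
    """Seed-discovery thresholds.

    HSPs (high-scoring segment pairs) from the self-alignment must reach
    ``min_hsp_score`` (internal scoring units) over >= ``min_hsp_len`` bp;
    their query intervals are single-linkage clustered at
    ``reciprocal_overlap``; clusters with >= ``min_support`` HSPs yield a
    consensus seed.
    """

    min_hsp_score: float = 100.0
    min_hsp_len: int = 80
    min_support: int = 3
    reciprocal_overlap: float = 0.80
    min_seed_len: int = 80
    max_cluster_members: int = 30  # star-consensus cost cap


@dataclass
class RepeatSeed:
    """A de novo consensus used as a library element for re-mapping."""

    id: str
    consensus: str
    n_support: int
    method: str  # "selfalign" | "structural"

    def __post_init__(self) -> None:
        if len(self.consensus) < 80:
            raise ValueError("seed consensus must be >= 80 bp")


@dataclass
class FullLengthInstance:
    """A genomic copy that passed the 80-80-80 filter against its seed."""

    interval: GenomeInterval
    seed_id: str
    sequence: str  # extracted genomic sequence, seed orientation
    sim: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatCluster:
    """An 80%-identity cluster of full-length instances (a subfamily)."""

    id: str
    centroid: FullLengthInstance
    members: list[FullLengthInstance]
    consensus: str = ""

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class RepeatFamily:
    """Clusters merged by all-vs-all consensus alignment."""

    name: str
    clusters: list[RepeatCluster]
    representative: str = ""
    classification: Classification = field(default_factory=Classification)

    @property
    def copy_count(self) -> int:
        return sum(c.n_members for c in self.clusters)

    @property
    def coverage_bp(self) -> int:
        return sum(len(m) for c in self.clusters for m in c.members)

    def pct_of_set(self, set_len: int) -> float:
        return 100.0 * self.coverage_bp / set_len if set_len else 0.0

    def representative_cluster(self) -> RepeatCluster:
        return next(c for c in self.clusters if c.id == self.representative)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _cluster_hsp_intervals(
    intervals: list[GenomeInterval],
    reciprocal: float,
) -> list[list[int]]:
    """Single-linkage clusters of intervals with reciprocal overlap >=
    ``reciprocal`` on the same sequence."""
    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i].seq_id, intervals[i].start,
                                  intervals[i].end))
    uf = _UnionFind(len(intervals))
    for a_pos, i in enumerate(order):
        iv_i = intervals[i]
        for j in order[a_pos + 1:]:
            iv_j = intervals[j]
            if iv_j.seq_id != iv_i.seq_id or iv_j.start >= iv_i.end:
                break
            ov = iv_i.overlap(iv_j)
            if ov >= reciprocal * len(iv_i) and ov >= reciprocal * len(iv_j):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(uf.find(i), []).append(i)
    return [sorted(g) for _, g in sorted(groups.items())]


def discover_seeds(seqs: SequenceSet,
                   params: SeedParams = SeedParams(),
                   engine: str = "auto") -> list[RepeatSeed]:
    """Repeat seeds from self-alignment plus a structural LTR pass.

    All-vs-all local alignment of the set against itself (identity
    diagonal removed); qualifying HSP query intervals are single-linkage
    clustered with reciprocal overlap >= 80%; clusters with >= 3
    supporting HSPs yield a majority star consensus. A structural pass
    runs the LTR-pair detector over every cluster span (regardless of
    support) and adds seeds for LTR-bounded spans.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    sequences = {rec.id: rec.residues for rec in seqs}
    hits = _blast.search(sequences, sequences,
                         min_score=params.min_hsp_score, engine=engine)
    hits = _blast.drop_self_hits(hits)
    # drop same-sequence hits whose query and subject spans overlap or
    # nearly abut (a sequence matching a shifted copy of itself): that is
    # the signature of a tandem array, which belongs to the tandem
    # detector, not to interspersed-repeat seeding. A genuine terminal
    # repeat pair is separated by the element's interior, which is wider
    # than the repeat itself.
    def _tandem_like(h) -> bool:
        if h.query_id != h.subject_name:
            return False
        gap = max(h.qstart, h.sstart) - min(h.qend, h.send)
        return gap < min(h.query_span, h.subject_span)

    hits = [h for h in hits if not _tandem_like(h)]
    hsps = [h for h in hits if h.query_span >= params.min_hsp_len]
    intervals = [GenomeInterval(h.query_id, h.qstart, h.qend) for h in hsps]
    clusters = _cluster_hsp_intervals(intervals, params.reciprocal_overlap)

    seeds: list[RepeatSeed] = []
    for gi, group in enumerate(clusters):
        ivs = [intervals[i] for i in group]
        support = len(group)
        # representative span per cluster: the widest member interval
        span = max(ivs, key=lambda iv: (len(iv), -iv.start))
        members = [seqs[iv.seq_id].residues[iv.start:iv.end] for iv in ivs]
        members.sort(key=len, reverse=True)
        members = members[:params.max_cluster_members]
        if support >= params.min_support:
            consensus = star_consensus(members, members[0])
            if len(consensus) >= params.min_seed_len:
                seeds.append(RepeatSeed(
                    id=f"seed{len(seeds):04d}", consensus=consensus,
                    n_support=support, method="selfalign",
                ))
        # structural pass: LTR-bounded spans qualify even at support 1
        margin = 200
        rec = seqs[span.seq_id]
        lo = max(0, span.start - margin)
        hi = min(len(rec), span.end + margin)
        candidate = rec.residues[lo:hi]
        pair = detect_ltr_pair(candidate)
        if pair is not None and pair.orientation == "direct":
            bounded = candidate[pair.left[0]:pair.right[1]]
            if len(bounded) >= params.min_seed_len:
                seeds.append(RepeatSeed(
                    id=f"seed{len(seeds):04d}", consensus=bounded,
                    n_support=support, method="structural",
                ))
    return _dedupe_seeds(seeds)


def _tandem_dominated(consensus: str, max_frac: float = 0.60) -> bool:
    """True when tandem arrays cover most of a candidate consensus;
    such consensi are satellite repeats, not interspersed elements."""
    from .seqio import GenomeInterval, merged_coverage
    from .tandem import detect_tandem

    arrays = detect_tandem(consensus)
    if not arrays:
        return False
    covered = merged_coverage([a.interval for a in arrays])
    return covered >= max_frac * len(consensus)


def _dedupe_seeds(seeds: list[RepeatSeed],
                  identity: float = 0.90) -> list[RepeatSeed]:
    """Greedy removal of near-identical seeds (longest kept)."""
    seeds = [s for s in seeds if not _tandem_dominated(s.consensus)]
    ordered = sorted(seeds, key=lambda s: (-len(s.consensus), s.id))
    kept: list[RepeatSeed] = []
    for seed in ordered:
        dup = False
        for other in kept:
            if abs(len(other.consensus) - len(seed.consensus)) \
                    > 0.2 * len(other.consensus):
                continue
            if global_identity(seed.consensus, other.consensus) >= identity:
                dup = True
                break
        if not dup:
            kept.append(seed)
    kept.sort(key=lambda s: s.id)
    return kept


def seeds_as_library(seeds: list[RepeatSeed]) -> RepeatLibrary:
    return RepeatLibrary([
        RepeatLibraryEntry(name=s.id, sequence=s.consensus)
        for s in seeds
    ])


def map_seeds(seeds: list[RepeatSeed], seqs: SequenceSet,
              filter_params: FilterParams = FilterParams(),
              engine: str = "auto") -> list[FullLengthInstance]:
    """Re-map seeds onto the reference and extract full-length instances.

    Seeds act as the library of a non-redundant homology search; hits
    surviving the 80-80-80 filter (seed as the reference) become
    instances, extracted in seed orientation.
    """
    if not seeds:
        return []
    library = seeds_as_library(seeds)
    hits = _blast.search({rec.id: rec.residues for rec in seqs},
                         library.sequences(), min_score=50.0, engine=engine)
    for h in hits:
        sim_metric(h)
    hits = full_length_filter(hits, library, filter_params)
    hits = nonredundant(hits)
    instances = []
    for h in hits:
        seq = seqs[h.query_id].residues[h.qstart:h.qend]
        if h.strand == "-":
            seq = revcomp(seq)
        instances.append(FullLengthInstance(
            interval=GenomeInterval(h.query_id, h.qstart, h.qend, h.strand),
            seed_id=h.subject_name, sequence=seq, sim=h.sim,
        ))
    instances.sort(key=lambda i: (i.interval.seq_id, i.interval.start))
    return instances


def cluster_instances(instances: list[FullLengthInstance],
                      id_threshold: float = 0.80) -> list[RepeatCluster]:
    """Greedy centroid clustering of instances at a global identity
    threshold.

    Instances are sorted by length descending (ties by genomic position);
    each joins the first existing centroid with global identity (matches
    over all alignment columns, end gaps penalized) >= threshold, else
    founds a new cluster. Deterministic by the fixed sort order; order
    independence is not promised.
    """
    ordered = sorted(
        instances,
        key=lambda i: (-len(i), i.interval.seq_id, i.interval.start),
    )
    clusters: list[RepeatCluster] = []
    for inst in ordered:
        placed = False
        for cluster in clusters:
            # a short instance cannot reach the identity bound against a
            # much longer centroid (end gaps are penalized columns)
            if len(inst) < id_threshold * len(cluster.centroid.sequence):
                continue
            ident = global_identity(inst.sequence,
                                    cluster.centroid.sequence)
            if ident >= id_threshold:
                cluster.members.append(inst)
                placed = True
                break
        if not placed:
            clusters.append(RepeatCluster(
                id=f"cluster{len(clusters):04d}",
                centroid=inst, members=[inst],
            ))
    return clusters


def cluster_consensus(cluster: RepeatCluster) -> str:
    """Majority consensus of a cluster via a star alignment to the
    centroid; the consensus is stored on the cluster and returned."""
    if cluster.n_members == 1:
        cluster.consensus = cluster.centroid.sequence
    else:
        cluster.consensus = star_consensus(
            [m.sequence for m in cluster.members],
            cluster.centroid.sequence,
        )
    return cluster.consensus


def build_families(clusters: list[RepeatCluster],
                   filter_params: FilterParams = FilterParams(),
                   engine: str = "auto",
                   library: RepeatLibrary | None = None
                   ) -> list[RepeatFamily]:
    """Merge clusters into families by all-vs-all consensus alignment.

    Two clusters are linked when a local alignment of their consensi
    satisfies the 80-80-80 standard with the shorter consensus as the
    reference; families are the connected components. The representative
    cluster has the most full-length members (ties: longer consensus).
    Families matching a classified library entry inherit its name.
    """
    for c in clusters:
        if not c.consensus:
            cluster_consensus(c)
    n = len(clusters)
    uf = _UnionFind(n)
    consensi = {c.id: c.consensus for c in clusters}
    idx = {c.id: i for i, c in enumerate(clusters)}
    hits = _blast.search(consensi, consensi, min_score=50.0, engine=engine)
    hits = _blast.drop_self_hits(hits)
    for h in hits:
        if h.query_id == h.subject_name:
            continue
        qlen = len(consensi[h.query_id])
        slen = len(consensi[h.subject_name])
        # evaluate coverage on the shorter consensus as the reference
        ref_span = h.subject_span if slen <= qlen else h.query_span
        ref_len = min(qlen, slen)
        sim_metric(h)
        if (ref_span > filter_params.min_len
                and h.sim >= filter_params.min_sim
                and ref_span / ref_len >= filter_params.min_subject_cov):
            uf.union(idx[h.query_id], idx[h.subject_name])
    groups: dict[int, list[RepeatCluster]] = {}
    for c in clusters:
        groups.setdefault(uf.find(idx[c.id]), []).append(c)
    families: list[RepeatFamily] = []
    for _, group in sorted(groups.items()):
        rep = max(group, key=lambda c: (c.n_members, len(c.consensus)))
        families.append(RepeatFamily(
            name="", clusters=group, representative=rep.id,
        ))
    families.sort(key=lambda f: (-f.coverage_bp, f.clusters[0].id))
    for i, fam in enumerate(families):
        fam.name = f"family{i:03d}"
        if library is not None:
            fam.name, fam.classification = _match_library(fam, library,
                                                          filter_params)
    return families


def _match_library(family: RepeatFamily, library: RepeatLibrary,
                   filter_params: FilterParams) -> tuple[str, Classification]:
    """Known-library name for a family whose representative consensus
    passes the full-length standard against a library entry."""
    from .classify import classify_repeat

    consensus = family.representative_cluster().consensus
    cls = classify_repeat(consensus, library, params=filter_params)
    if cls.evidence == "nucleotide" and cls.family is not None:
        return cls.family, cls
    return family.name, cls


def family_instances(families: list[RepeatFamily]) -> list[Annotation]:
    """GFF-ready annotations of every instance, labeled by family."""
    anns = []
    for fam in families:
        tag = fam.classification.header_tag() \
            if not fam.classification.is_unknown() else "unknown"
        for cluster in fam.clusters:
            for m in cluster.members:
                anns.append(Annotation(
                    interval=m.interval,
                    category=tag,
                    score=max(0.0, m.sim * 100.0),
                    attributes={"family": fam.name, "cluster": cluster.id,
                                "seed": m.seed_id},
                ))
    anns.sort(key=lambda a: (a.interval.seq_id, a.interval.start))
    return anns


def family_report(families: list[RepeatFamily],
                  seqs: SequenceSet) -> pd.DataFrame:
    """Per-family coverage table sorted by coverage, with a totals row.

    Columns: family, full_length_copies, length_bp, pct_of_set (percent of
    the set's non-N length, two decimals).
    """
    set_len = seqs.total_non_n
    rows = [
        {
            "family": fam.name,
            "full_length_copies": fam.copy_count,
            "length_bp": fam.coverage_bp,
            "pct_of_set": round(fam.pct_of_set(set_len), 2),
        }
        for fam in sorted(families, key=lambda f: -f.coverage_bp)
    ]
    totals = {
        "family": "Total",
        "full_length_copies": sum(r["full_length_copies"] for r in rows),
        "length_bp": sum(r["length_bp"] for r in rows),
        "pct_of_set": round(sum(r["pct_of_set"] for r in rows), 2),
    }
    return pd.DataFrame(rows + [totals],
                        columns=["family", "full_length_copies",
                                 "length_bp", "pct_of_set"])


def denovo_pipeline(seqs: SequenceSet,
                    seed_params: SeedParams = SeedParams(),
                    filter_params: FilterParams = FilterParams(),
                    engine: str = "auto",
                    library: RepeatLibrary | None = None
                    ) -> tuple[list[RepeatSeed], list[FullLengthInstance],
                               list[RepeatCluster], list[RepeatFamily]]:
    """discover -> map -> cluster -> consensus -> families, end to end."""
    seeds = discover_seeds(seqs, seed_params, engine=engine)
    instances = map_seeds(seeds, seqs, filter_params, engine=engine)
    clusters = cluster_instances(instances)
    for c in clusters:
        cluster_consensus(c)
    families = build_families(clusters, filter_params, engine=engine,
                              library=library)
    return seeds, instances, clusters, families
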