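"""Parameter-recovery benchmarks on simulated genomes.

Defines the standard validation conditions — 3 sequences of 200 kbp with K
planted element families (>= 8 full copies each, per-copy identity ~0.95,
mutually unrelated masters) and 20 planted tandem arrays spanning the
micro/mini/satellite period range — and the scoring of a pipeline run
against the exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import global_identity
from .denovo import denovo_pipeline, family_instances
from .report import content_report
from .seqio import revcomp
from .simulate import (FamilySpec, GenomeSpec, TandemSpec,
                       simulate_with_masters)
from .tandem import (TandemArray, detect_tandem_set, primitive_period,
                     resolve_tandem_overlaps)

TANDEM_PERIODS = [2, 3, 4, 5, 6, 8, 10, 15, 21, 25, 30, 40, 50, 60, 80,
                  100, 120, 150, 200, 300]


def _random_motif(period: int, rng: np.random.Generator) -> str:
    """A primitive (non-self-periodic) motif of the requested period."""
    while True:
        motif = "".join(rng.choice(list("ACGT"), size=period))
        if primitive_period(motif) == period:
            return motif


def study_spec(k: int, seed: int, n_sequences: int = 3,
               seq_len: int = 200_000, copies_per_family: int = 10,
               sub_rate: float = 0.05,
               tandem_sub_rate: float = 0.02) -> GenomeSpec:
    """The benchmark genome: K families plus 20 tandem arrays."""
    rng = np.random.default_rng(seed + 10_007)
    families = []
    for i in range(k):
        element_length = int(rng.integers(1500, 3001))
        order = "LTR" if i % 2 == 0 else ("TIR" if i % 4 == 1 else
                                          "LINE-like")
        ltr = int(rng.integers(150, 301)) if order in ("LTR", "TIR") \
            else None
        families.append(FamilySpec(
            name=f"fam{i}", order=order, element_length=element_length,
            ltr_length=ltr, copy_number=copies_per_family,
            sub_rate=sub_rate))
    tandems = []
    for period in TANDEM_PERIODS:
        copies = max(3.0, float(int(np.ceil(100 / period))))
        tandems.append(TandemSpec(motif=_random_motif(period, rng),
                                  copies=copies,
                                  sub_rate=tandem_sub_rate))
    return GenomeSpec(n_sequences=n_sequences,
                      length_distribution=[seq_len] * n_sequences,
                      gc=0.38, seed=seed, families=families,
                      tandems=tandems)


@dataclass
class RecoveryResult:
    k_planted: int
    families_recovered: int
    copy_count_errors: list[int]        # |recovered - planted| per family
    family_identities: list[float]      # consensus vs matched master
    tandem_planted: int
    tandem_recovered: int
    planted_pct: float
    estimated_pct: float

    @property
    def tandem_recovery_rate(self) -> float:
        return self.tandem_recovered / self.tandem_planted \
            if self.tandem_planted else 1.0

    @property
    def content_rel_error(self) -> float:
        if self.planted_pct == 0:
            return 0.0
        return abs(self.estimated_pct - self.planted_pct) / self.planted_pct


def _match_families_to_masters(families, masters,
                               min_identity: float = 0.70):
    """Greedy one-to-one assignment of recovered families to planted
    masters by representative-consensus identity (either strand)."""
    pairs = []
    for fi, fam in enumerate(families):
        consensus = fam.representative_cluster().consensus
        for name, master in masters.items():
            ident = max(global_identity(consensus, master),
                        global_identity(consensus, revcomp(master)))
            pairs.append((ident, fi, name))
    pairs.sort(reverse=True)
    used_f, used_m, matches = set(), set(), {}
    for ident, fi, name in pairs:
        if ident < min_identity or fi in used_f or name in used_m:
            continue
        used_f.add(fi)
        used_m.add(name)
        matches[fi] = (name, ident)
    return matches


def _tandem_recovered(truth_rows, detected: list[TandemArray]) -> int:
    """Planted arrays recovered with the correct canonical period (the
    primitive period of the planted motif, or an integer multiple)."""
    n = 0
    for _, row in truth_rows.iterrows():
        base = primitive_period(row["name"])
        for arr in detected:
            if arr.interval.seq_id != row["seq_id"]:
                continue
            ov = min(arr.interval.end, row["end"]) \
                - max(arr.interval.start, row["start"])
            if ov < 0.5 * (row["end"] - row["start"]):
                continue
            if arr.period_size % base == 0:
                n += 1
                break
    return n


def run_recovery(k: int, seed: int, **spec_kw) -> RecoveryResult:
    """Simulate the benchmark genome and score the full pipeline on it."""
    spec = study_spec(k, seed, **spec_kw)
    seqs, truth, masters = simulate_with_masters(spec)

    arrays = resolve_tandem_overlaps(detect_tandem_set(seqs))
    _seeds, _instances, _clusters, families = denovo_pipeline(seqs)
    fam_anns = family_instances(families)
    report = content_report(seqs, arrays, {"unfiltered": fam_anns})

    matches = _match_families_to_masters(families, masters)
    copy_errors, identities = [], []
    planted_copies = {f.name: f.copy_number for f in spec.families}
    for fi, (name, ident) in matches.items():
        copy_errors.append(abs(families[fi].copy_count
                               - planted_copies[name]))
        identities.append(ident)

    tandem_truth = truth.tandem_rows()
    planted_bp = truth.total_bp()
    planted_pct = 100.0 * planted_bp / seqs.total_non_n
    return RecoveryResult(
        k_planted=k,
        families_recovered=len(families),
        copy_count_errors=copy_errors,
        family_identities=identities,
        tandem_planted=len(tandem_truth),
        tandem_recovered=_tandem_recovered(tandem_truth, arrays),
        planted_pct=planted_pct,
        estimated_pct=report.total_repetitive_pct("unfiltered"),
    )
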