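"""Alignment hits, the sim metric, the 80-80-80 filter, coverage modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatscape.align import AlignmentHit, local_align
from repeatscape.homology import (CoverageReport, annotate_set,
                                  full_length_filter, gypsy_copia_ratio,
                                  nonredundant, read_blast_m8, sim_metric)
from repeatscape.library import (Classification, RepeatLibrary,
                                 RepeatLibraryEntry)
from repeatscape.seqio import revcomp
from repeatscape.simulate import (FamilySpec, GenomeSpec, random_sequence,
                                  simulate_with_masters)


def make_hit(**kw):
    defaults = dict(query_id="q", qstart=0, qend=100, subject_name="s",
                    sstart=0, send=100, strand="+", match_count=90,
                    alignment_length=100, query_gap_length=0,
                    subject_gap_length=0, gap_count=0, score=100.0)
    defaults.update(kw)
    return AlignmentHit(**defaults)


def _gotoh_local(a, b, match=3, mismatch=-4, open_=-5, extend=-2):
    """Independent affine-gap local-alignment oracle (Gotoh DP)."""
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + extend,
                          H[i][j - 1] + open_ + extend)
            F[i][j] = max(F[i - 1][j] + extend,
                          H[i - 1][j] + open_ + extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        seq = random_sequence(100, rng)
        hits = local_align(seq, seq, both_strands=False)
        assert hits[0].score == 300.0  # 100 x (+3)
        assert sim_metric(hits[0]) == 1.0

    def test_reverse_complement_strand(self, rng):
        seq = random_sequence(120, rng)
        hits = local_align(seq, revcomp(seq))
        best = hits[0]
        assert best.strand == "-"
        assert sim_metric(best) == 1.0

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_counts_consistency(self, rng):
        a = random_sequence(300, rng)
        b = random_sequence(300, rng, 0.5)
        # embed a shared, slightly diverged segment
        shared = random_sequence(120, rng)
        mutated = list(shared)
        mutated[30] = "A" if shared[30] != "A" else "C"
        a = a[:100] + shared + a[100:]
        b = b[:50] + "".join(mutated) + b[50:]
        hit = local_align(a, b, both_strands=False)[0]
        aligned_cols = (hit.alignment_length - hit.query_gap_length
                        - hit.subject_gap_length)
        assert hit.match_count <= aligned_cols
        assert hit.query_span <= hit.alignment_length
        assert hit.subject_span <= hit.alignment_length

    def test_multiple_hits_by_masking(self, rng):
        subject = random_sequence(150, rng)
        filler = random_sequence(200, rng, 0.5)
        query = subject[:60] + filler + subject[90:150]
        hits = local_align(query, subject, both_strands=False)
        assert len(hits) >= 2
        spans = sorted((h.qstart, h.qend) for h in hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping on the query

    def test_gotoh_oracle_on_short_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n, m = int(rng.integers(3, 11)), int(rng.integers(3, 11))
            a = random_sequence(n, rng, 0.5)
            b = random_sequence(m, rng, 0.5)
            want = _gotoh_local(a, b)
            hits = local_align(a, b, min_score=1, both_strands=False)
            got = hits[0].score if hits else 0
            assert got == want


class TestSimMetric:
    def test_ungapped_reduces_to_identity(self):
        hit = make_hit(match_count=90, alignment_length=100)
        assert sim_metric(hit) == pytest.approx(0.9)

    def test_gapped_formula(self):
        # 95 matches over 105 columns with a single 5-residue query gap:
        # 95 / (105 - 5 - 0 + 1) = 95/101
        hit = make_hit(match_count=95, alignment_length=105,
                       query_gap_length=5, gap_count=1)
        assert sim_metric(hit) == pytest.approx(95 / 101)

    def test_perfect_alignment(self):
        hit = make_hit(qend=80, send=80, match_count=80,
                       alignment_length=80)
        assert sim_metric(hit) == 1.0

    def test_nonpositive_denominator_error(self):
        hit = make_hit(match_count=0, alignment_length=10,
                       query_gap_length=5, subject_gap_length=5,
                       gap_count=0)
        with pytest.raises(ValueError):
            sim_metric(hit)

    @given(st.integers(min_value=1, max_value=500), st.data())
    @settings(derandomize=True, max_examples=100)
    def test_gap_free_equals_identity(self, length, data):
        matches = data.draw(st.integers(min_value=0, max_value=length))
        hit = make_hit(qend=length, send=length, match_count=matches,
                       alignment_length=length)
        assert sim_metric(hit) == pytest.approx(matches / length)


class TestBlastTabular:
    def _write(self, tmp_path, rows):
        p = tmp_path / "hits.m8"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_perfect_hit(self, tmp_path):
        p = self._write(tmp_path, [
            ("q", "s", 100.0, 80, 0, 0, 1, 80, 1, 80, 1e-30, 150.0)])
        hit = read_blast_m8(p)[0]
        assert hit.match_count == 80 and hit.sim == 1.0
        assert (hit.qstart, hit.qend) == (0, 80)

    def test_gap_reconstruction(self, tmp_path):
        # 105 columns, query span 100 -> 5 query-side gap residues
        p = self._write(tmp_path, [
            ("q", "s", 95.0, 105, 0, 1, 1, 100, 1, 105, 1e-30, 150.0)])
        hit = read_blast_m8(p)[0]
        assert hit.query_gap_length == 5
        assert hit.subject_gap_length == 0
        assert hit.gap_count == 1

    def test_minus_strand_convention(self, tmp_path):
        p = self._write(tmp_path, [
            ("q", "s", 100.0, 100, 0, 0, 1, 100, 200, 101, 1e-30, 180.0)])
        hit = read_blast_m8(p)[0]
        assert hit.strand == "-"
        assert (hit.sstart, hit.send) == (100, 200)

    def test_wrong_column_count_error(self, tmp_path):
        p = self._write(tmp_path, [("q", "s", 100.0, 80)])
        with pytest.raises(ValueError):
            read_blast_m8(p)

    def test_unknown_subject_error(self, tmp_path):
        p = self._write(tmp_path, [
            ("q", "nope", 100.0, 80, 0, 0, 1, 80, 1, 80, 1e-30, 150.0)])
        lib = RepeatLibrary([RepeatLibraryEntry("s", "ACGT" * 30)])
        with pytest.raises(KeyError):
            read_blast_m8(p, lib)


class TestFullLengthFilter:
    @pytest.fixture
    def library(self):
        return RepeatLibrary([RepeatLibraryEntry("s", "A" * 240)])

    def test_span_strictly_above_80(self, library):
        short = make_hit(send=79, match_count=79, alignment_length=79,
                         sim=1.0)
        exact = make_hit(send=80, match_count=80, alignment_length=80,
                         sim=1.0)
        assert full_length_filter([short], library) == []
        assert full_length_filter([exact], library) == []  # strict >80

    def test_coverage_and_sim(self, library):
        # span 200 of 240 (0.833 coverage), sim 0.85 -> kept
        good = make_hit(send=200, match_count=170, alignment_length=200,
                        sim=0.85)
        assert full_length_filter([good], library) == [good]
        low_sim = make_hit(send=200, match_count=158, alignment_length=200,
                           sim=0.79)
        assert full_length_filter([low_sim], library) == []
        low_cov = make_hit(send=190, match_count=180,
                           alignment_length=190, sim=0.95)
        assert full_length_filter([low_cov], library) == []  # 190/240 < 0.8

    def test_unknown_subject_error(self, library):
        hit = make_hit(subject_name="nope", sim=0.9)
        with pytest.raises(KeyError):
            full_length_filter([hit], library)


class TestNonRedundant:
    def test_colocated_highest_score_wins(self):
        a = make_hit(score=500.0)
        b = make_hit(score=300.0, subject_name="t")
        assert nonredundant([a, b]) == [a]

    def test_disjoint_kept(self):
        a = make_hit(score=500.0)
        b = make_hit(qstart=200, qend=300, score=300.0)
        assert len(nonredundant([a, b])) == 2

    def test_independent_reimplementation_oracle(self, rng):
        def oracle(hits):
            order = sorted(hits, key=lambda h: (-h.score, -h.query_span,
                                                h.subject_name, h.query_id,
                                                h.qstart, h.strand))
            acc = []
            for h in order:
                ov_ok = True
                for x in acc:
                    if h.query_id != x.query_id:
                        continue
                    ov = max(0, min(h.qend, x.qend)
                             - max(h.qstart, x.qstart))
                    if ov > 0.5 * h.query_span:
                        ov_ok = False
                        break
                if ov_ok:
                    acc.append(h)
            return sorted(acc, key=lambda h: (h.query_id, h.qstart, h.qend))
        for _ in range(25):
            hits = []
            for i in range(int(rng.integers(2, 11))):
                start = int(rng.integers(0, 300))
                end = start + int(rng.integers(30, 200))
                hits.append(make_hit(qstart=start, qend=end,
                                     subject_name=f"s{i}",
                                     score=float(rng.integers(50, 900))))
            got = nonredundant(hits)
            want = oracle(hits)
            assert [(g.qstart, g.qend, g.score) for g in got] == \
                [(w.qstart, w.qend, w.score) for w in want]


@pytest.fixture(scope="module")
def planted_genome():
    spec = GenomeSpec(
        n_sequences=2, length_distribution=(40_000, 50_000), seed=21,
        families=[
            FamilySpec("gyp", order="LTR", element_length=3000,
                       ltr_length=300, copy_number=6, sub_rate=0.05),
            FamilySpec("cop", order="LTR", element_length=2000,
                       ltr_length=200, copy_number=6, sub_rate=0.05),
        ])
    seqs, truth, masters = simulate_with_masters(spec)
    library = RepeatLibrary([
        RepeatLibraryEntry("gyp", masters["gyp"],
                           Classification("I", "LTR", "Gypsy", "gyp")),
        RepeatLibraryEntry("cop", masters["cop"],
                           Classification("I", "LTR", "Copia", "cop")),
    ])
    return seqs, truth, library


class TestAnnotateSet:
    def test_planted_family_coverage(self, planted_genome):
        seqs, truth, library = planted_genome
        _, report = annotate_set(seqs, library, mode="nonredundant",
                                 filtered=True)
        planted_pct = 100.0 * truth.total_bp("TE") / seqs.total_non_n
        assert report.total_pct == pytest.approx(planted_pct, rel=0.15)

    def test_unrelated_library_zero(self, planted_genome, rng):
        seqs, _, _ = planted_genome
        decoy = RepeatLibrary([RepeatLibraryEntry(
            "decoy", random_sequence(2000, rng),
            Classification("I", "LTR", "Gypsy", "decoy"))])
        _, report = annotate_set(seqs, decoy, mode="nonredundant",
                                 filtered=True)
        assert report.total_pct == 0.0

    def test_class_totals_conserved(self, planted_genome):
        _, _, library = planted_genome
        seqs, _, _ = planted_genome
        _, report = annotate_set(seqs, library, mode="redundant")
        by_class = report.by_class()
        by_order = report.by_order()
        for class_, bp in by_class.items():
            assert bp == sum(v for (c, _), v in by_order.items()
                             if c == class_)

    def test_filtered_within_unfiltered(self, planted_genome):
        seqs, _, library = planted_genome
        _, unf = annotate_set(seqs, library, mode="nonredundant")
        _, fil = annotate_set(seqs, library, mode="nonredundant",
                              filtered=True)
        for path, bp in fil.by_family().items():
            assert bp <= unf.by_family().get(path, 0)
        assert fil.total_bp <= unf.total_bp

    def test_filter_commutes_with_nonredundant(self, planted_genome):
        seqs, _, library = planted_genome
        hits_r, _ = annotate_set(seqs, library, mode="redundant",
                                 filtered=True)
        hits_nr, _ = annotate_set(seqs, library, mode="nonredundant",
                                  filtered=True)
        spans_r = {(a.interval.seq_id, a.interval.start, a.interval.end)
                   for a in hits_r}
        spans_nr = {(a.interval.seq_id, a.interval.start, a.interval.end)
                    for a in hits_nr}
        assert spans_nr <= spans_r

    def test_empty_library_error(self, planted_genome):
        seqs, _, _ = planted_genome
        with pytest.raises(ValueError):
            annotate_set(seqs, RepeatLibrary([]), mode="redundant")


class TestGypsyCopia:
    def _report(self, gypsy_bp, copia_bp, set_len=1_000_000):
        return CoverageReport(
            paths={("I", "LTR", "Gypsy", "g1"): gypsy_bp,
                   ("I", "LTR", "Copia", "c1"): copia_bp},
            set_len=set_len)

    def test_study_ratio(self):
        # the printed coverages 11.97% Gypsy / 6.27% Copia give 1.9:1
        report = self._report(119_700, 62_700)
        assert gypsy_copia_ratio(report) == 1.9

    def test_equal_coverage(self):
        assert gypsy_copia_ratio(self._report(1000, 1000)) == 1.0

    def test_zero_copia_undefined(self):
        assert gypsy_copia_ratio(self._report(1000, 0)) is None
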