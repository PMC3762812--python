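"""Seed discovery, instance mapping, clustering, family formation."""

import pytest

from repeatscape.align import global_identity
from repeatscape.denovo import (FullLengthInstance, RepeatCluster,
                                RepeatFamily, RepeatSeed, build_families,
                                cluster_consensus, cluster_instances,
                                discover_seeds, family_report, map_seeds)
from repeatscape.seqio import (GenomeInterval, SequenceRecord, SequenceSet,
                               revcomp)
from repeatscape.simulate import (FamilySpec, GenomeSpec, mutate_copy,
                                  random_sequence, simulate_with_masters)


def _identity_to_master(seq, master):
    return max(global_identity(seq, master),
               global_identity(seq, revcomp(master)))


def _planted(seed, families, n_sequences=3, lengths=(40_000, 50_000)):
    spec = GenomeSpec(n_sequences=n_sequences,
                      length_distribution=lengths, seed=seed,
                      families=families)
    return simulate_with_masters(spec)


def _inst(seq, seq_id="s", start=0, seed_id="seed0000"):
    return FullLengthInstance(
        interval=GenomeInterval(seq_id, start, start + len(seq)),
        seed_id=seed_id, sequence=seq, sim=0.95)


class TestDiscoverSeeds:
    def test_planted_family_yields_matching_seed(self):
        seqs, truth, masters = _planted(31, [FamilySpec(
            "f", order="LTR", element_length=2000, ltr_length=200,
            copy_number=10, sub_rate=0.05)])
        seeds = discover_seeds(seqs)
        assert seeds
        assert any(_identity_to_master(s.consensus, masters["f"]) >= 0.80
                   for s in seeds)

    def test_repeat_free_genome_no_selfalign_seeds(self):
        for seed in range(10):
            spec = GenomeSpec(n_sequences=2,
                              length_distribution=(15_000, 20_000),
                              seed=seed)
            seqs, _, _ = simulate_with_masters(spec)
            seeds = discover_seeds(seqs)
            assert [s for s in seeds if s.method == "selfalign"] == []

    def test_two_distant_families_two_seeds(self):
        seqs, truth, masters = _planted(33, [
            FamilySpec("a", order="LTR", element_length=2000,
                       ltr_length=200, copy_number=8, sub_rate=0.05),
            FamilySpec("b", order="LINE-like", element_length=1200,
                       ltr_length=None, copy_number=8, sub_rate=0.05),
        ])
        assert _identity_to_master(masters["a"], masters["b"]) < 0.6
        seeds = discover_seeds(seqs)
        hit_a = any(_identity_to_master(s.consensus, masters["a"]) >= 0.8
                    for s in seeds)
        hit_b = any(_identity_to_master(s.consensus, masters["b"]) >= 0.8
                    for s in seeds)
        assert hit_a and hit_b

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            discover_seeds(SequenceSet([]))

    def test_seed_minimum_length(self):
        with pytest.raises(ValueError):
            RepeatSeed(id="x", consensus="ACGT", n_support=3,
                       method="selfalign")


class TestMapSeeds:
    def test_full_copies_recovered(self, rng):
        master = random_sequence(1500, rng)
        bg = [random_sequence(30_000, rng) for _ in range(2)]
        placed = 0
        seq_parts = []
        for i, b in enumerate(bg):
            parts, pos = [], 0
            for k in range(5):
                at = 3000 + k * 5000
                copy, _ = mutate_copy(master, 0.05, 0.0, rng)
                parts.append(b[pos:at] + copy)
                pos = at + len(copy)
                placed += 1
            parts.append(b[pos:])
            seq_parts.append("".join(parts))
        seqs = SequenceSet([SequenceRecord(f"s{i}", s)
                            for i, s in enumerate(seq_parts)])
        seeds = [RepeatSeed(id="seed0000", consensus=master, n_support=5,
                            method="selfalign")]
        instances = map_seeds(seeds, seqs)
        assert len(instances) == placed == 10

    def test_unmatched_seed_no_instances(self, rng):
        seqs = SequenceSet([SequenceRecord("s", random_sequence(20_000,
                                                                rng))])
        seeds = [RepeatSeed(id="x", consensus=random_sequence(1000, rng),
                            n_support=3, method="selfalign")]
        assert map_seeds(seeds, seqs) == []

    def test_truncated_copy_excluded(self, rng):
        master = random_sequence(2000, rng)
        half = master[1000:]  # 50% 5'-truncated copy
        bg = random_sequence(30_000, rng)
        genome = bg[:5000] + master + bg[5000:15000] + half + bg[15000:]
        seqs = SequenceSet([SequenceRecord("s", genome)])
        seeds = [RepeatSeed(id="seed0000", consensus=master, n_support=3,
                            method="selfalign")]
        instances = map_seeds(seeds, seqs)
        assert len(instances) == 1  # the fragment fails 0.8 coverage
        assert instances[0].interval.start == 5000


class TestClusterInstances:
    def test_identical_sequences_one_cluster(self, rng):
        seq = random_sequence(500, rng)
        clusters = cluster_instances([_inst(seq, start=i * 1000)
                                      for i in range(5)])
        assert len(clusters) == 1 and clusters[0].n_members == 5

    def test_distant_pair_two_singletons(self, rng):
        a = random_sequence(500, rng)
        b, ident = mutate_copy(a, 0.25, 0.0, rng)
        assert global_identity(a, b) < 0.80
        clusters = cluster_instances([_inst(a), _inst(b, start=1000)])
        assert len(clusters) == 2

    def test_deterministic_under_input_order(self, rng):
        base = random_sequence(600, rng)
        instances = []
        for i in range(6):
            copy, _ = mutate_copy(base, 0.05, 0.0, rng)
            instances.append(_inst(copy, start=i * 1000))
        a = cluster_instances(list(instances))
        b = cluster_instances(list(reversed(instances)))
        key = lambda cs: [sorted(m.interval.start for m in c.members)
                          for c in cs]
        assert key(a) == key(b)

    def test_every_instance_in_exactly_one_cluster(self, rng):
        base = random_sequence(800, rng)
        instances = []
        for i in range(12):
            copy, _ = mutate_copy(base, 0.10 if i % 2 else 0.02, 0.0, rng)
            instances.append(_inst(copy, start=i * 1000))
        clusters = cluster_instances(instances)
        seen = [m.interval.start for c in clusters for m in c.members]
        assert sorted(seen) == sorted(i.interval.start for i in instances)


class TestClusterConsensus:
    def test_singleton(self, rng):
        inst = _inst(random_sequence(300, rng))
        cluster = RepeatCluster(id="c", centroid=inst, members=[inst])
        assert cluster_consensus(cluster) == inst.sequence

    def test_majority_vote_single_site(self, rng):
        base = random_sequence(300, rng)
        i = 150
        variant = base[:i] + ("G" if base[i] != "G" else "T") + base[i + 1:]
        members = [_inst(base, start=0), _inst(base, start=1000),
                   _inst(variant, start=2000)]
        cluster = RepeatCluster(id="c", centroid=members[0],
                                members=members)
        assert cluster_consensus(cluster) == base

    def test_consensus_error_reduction(self, rng):
        master = random_sequence(1000, rng)
        members = []
        for i in range(7):
            copy, _ = mutate_copy(master, 0.05, 0.0, rng)
            members.append(_inst(copy, start=i * 2000))
        cluster = RepeatCluster(id="c", centroid=members[0],
                                members=members)
        consensus = cluster_consensus(cluster)
        best_member = max(global_identity(m.sequence, master)
                          for m in members)
        assert global_identity(consensus, master) >= best_member


class TestBuildFamilies:
    def test_split_clusters_merged(self, rng):
        # two clusters of the same family (both consensi near the master)
        master = random_sequence(1500, rng)
        clusters = []
        for ci in range(2):
            members = []
            for i in range(3):
                copy, _ = mutate_copy(master, 0.06, 0.0, rng)
                members.append(_inst(copy, start=(ci * 10 + i) * 2000))
            clusters.append(RepeatCluster(id=f"c{ci}", centroid=members[0],
                                          members=members))
        families = build_families(clusters)
        assert len(families) == 1
        assert families[0].copy_count == 6

    def test_unrelated_clusters_stay_separate(self, rng):
        clusters = []
        for ci in range(2):
            seq = random_sequence(1200, rng)
            inst = _inst(seq, start=ci * 5000)
            clusters.append(RepeatCluster(id=f"c{ci}", centroid=inst,
                                          members=[inst]))
        assert len(build_families(clusters)) == 2

    def test_coverage_summation_rule(self, rng):
        a = _inst(random_sequence(100, rng))
        b = _inst(random_sequence(200, rng), start=1000)
        cluster = RepeatCluster(id="c", centroid=b, members=[a, b],
                                consensus=b.sequence)
        fam = RepeatFamily(name="f", clusters=[cluster],
                           representative="c")
        assert fam.coverage_bp == 300
        assert fam.copy_count == 2

    def test_partition_property(self, rng):
        base1, base2 = (random_sequence(900, rng) for _ in range(2))
        instances = []
        for i in range(4):
            c1, _ = mutate_copy(base1, 0.05, 0.0, rng)
            c2, _ = mutate_copy(base2, 0.05, 0.0, rng)
            instances += [_inst(c1, start=i * 4000),
                          _inst(c2, start=i * 4000 + 2000)]
        clusters = cluster_instances(instances)
        families = build_families(clusters)
        cluster_ids = [c.id for f in families for c in f.clusters]
        assert sorted(cluster_ids) == sorted(c.id for c in clusters)
        member_keys = [m.interval.start for f in families
                       for c in f.clusters for m in c.members]
        assert sorted(member_keys) == \
            sorted(i.interval.start for i in instances)

    def test_representative_has_most_members(self, rng):
        base = random_sequence(1000, rng)
        small = [_inst(mutate_copy(base, 0.05, 0.0, rng)[0], start=i * 2000)
                 for i in range(2)]
        large = [_inst(mutate_copy(base, 0.05, 0.0, rng)[0],
                       start=10_000 + i * 2000) for i in range(4)]
        clusters = [
            RepeatCluster(id="small", centroid=small[0], members=small),
            RepeatCluster(id="large", centroid=large[0], members=large),
        ]
        families = build_families(clusters)
        assert len(families) == 1
        assert families[0].representative == "large"


class TestFamilyReport:
    def test_totals_by_summation(self, rng):
        fams = []
        for fi, n in enumerate((3, 2)):
            members = [_inst(random_sequence(400, rng), start=i * 1000)
                       for i in range(n)]
            cluster = RepeatCluster(id=f"c{fi}", centroid=members[0],
                                    members=members,
                                    consensus=members[0].sequence)
            fams.append(RepeatFamily(name=f"f{fi}", clusters=[cluster],
                                     representative=f"c{fi}"))
        seqs = SequenceSet([SequenceRecord("s", "A" * 100_000)])
        table = family_report(fams, seqs)
        totals = table[table["family"] == "Total"].iloc[0]
        body = table[table["family"] != "Total"]
        assert totals["full_length_copies"] == \
            body["full_length_copies"].sum() == 5
        assert totals["length_bp"] == body["length_bp"].sum() == 2000

    def test_empty(self):
        seqs = SequenceSet([SequenceRecord("s", "A" * 1000)])
        table = family_report([], seqs)
        assert list(table["family"]) == ["Total"]
        assert table.iloc[0]["length_bp"] == 0
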