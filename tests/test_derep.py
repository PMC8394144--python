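"""Dereplication: coverage rule, fragment ANI, linkage clustering, merging,
non-redundant counting, country-specific species and depth pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magcatkit import synthdata
from magcatkit.derep import (
    SpeciesCluster,
    average_linkage_cluster,
    count_nonredundant,
    country_specific_species,
    coverage_cutoff,
    fragment_ani,
    merge_catalog,
    pair_conspecific_across_depths,
    two_step_species_clustering,
)
from magcatkit.quality import GenomeBin
from oracles import brute_force_partitions


class TestCoverageCutoff:
    @pytest.mark.parametrize(
        "ca, cb, expected",
        [(1.0, 1.0, 0.8), (0.5, 0.5, 0.25), (0.9, 1.0, 0.8), (0.6, 0.7, 0.42)],
    )
    def test_rule(self, ca, cb, expected):
        assert coverage_cutoff(ca, cb) == pytest.approx(expected)

    def test_zero_completeness_rejected(self):
        with pytest.raises(ValueError):
            coverage_cutoff(0.0, 0.5)


class TestFragmentAni:
    def test_identical_genomes(self, ancestors_50k):
        a = GenomeBin(bin_id="a", contigs=[ancestors_50k[0]])
        b = GenomeBin(bin_id="b", contigs=[ancestors_50k[0]])
        res = fragment_ani(a, b)
        assert res.ani == pytest.approx(1.0, abs=1e-6)
        assert res.coverage == pytest.approx(1.0, abs=0.01)
        assert res.passed_coverage

    def test_planted_divergence_recovered(self, conspecific_pair_200k):
        anc, evolved, positions = conspecific_pair_200k
        res = fragment_ani(
            GenomeBin(bin_id="q", contigs=[evolved]),
            GenomeBin(bin_id="r", contigs=[anc]),
        )
        true_ani = 1 - len(positions) / len(anc)
        assert res.ani == pytest.approx(true_ani, abs=0.005)
        assert res.ani == pytest.approx(0.97, abs=0.005)

    def test_unrelated_genomes_fail_coverage(self, ancestors_50k):
        a = GenomeBin(bin_id="a", contigs=[ancestors_50k[0]])
        b = GenomeBin(bin_id="b", contigs=[ancestors_50k[1]])
        res = fragment_ani(a, b)
        assert not res.passed_coverage
        assert np.isnan(res.ani) or res.coverage < 0.05

    def test_reverse_complement_maps(self, ancestors_50k):
        rc = ancestors_50k[0].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        res = fragment_ani(
            GenomeBin(bin_id="q", contigs=[rc]),
            GenomeBin(bin_id="r", contigs=[ancestors_50k[0]]),
        )
        assert res.ani == pytest.approx(1.0, abs=1e-6)

    def test_coverage_gating_on_disjoint_halves(self, ancestors_50k):
        """Two half-complete bins with non-overlapping content split by design."""
        g = ancestors_50k[0]
        half = len(g) // 2
        a = GenomeBin(bin_id="a", contigs=[g[:half]], completeness=50.0)
        b = GenomeBin(bin_id="b", contigs=[g[half:]], completeness=50.0)
        res = fragment_ani(a, b)  # cutoff = 0.25, overlap ~ 0
        assert not res.passed_coverage

    def test_short_fragment_length_rejected(self, ancestors_50k):
        a = GenomeBin(bin_id="a", contigs=[ancestors_50k[0]])
        with pytest.raises(ValueError):
            fragment_ani(a, a, frag_len=100)


class TestAverageLinkage:
    def test_all_zero_distances_single_cluster(self):
        d = np.zeros((4, 4))
        assert average_linkage_cluster(d, 0.2) == [{0, 1, 2, 3}]

    def test_three_items_matches_brute_force(self):
        d = np.array([[0, 0.01, 0.9], [0.01, 0, 0.9], [0.9, 0.9, 0]])
        got = average_linkage_cluster(d, 0.2)
        assert sorted(map(sorted, got)) == [[0, 1], [2]]
        # oracle: best valid partition (every within-cluster mean link <= cutoff)
        valid = []
        for part in brute_force_partitions(3):
            ok = all(
                np.mean([d[i, j] for i, j in itertools.combinations(grp, 2)]) <= 0.2
                for grp in part
                if len(grp) > 1
            )
            if ok:
                valid.append(part)
        assert any(sorted(map(sorted, p)) == [[0, 1], [2]] for p in valid)

    def test_cutoff_below_min_distance_all_singletons(self):
        d = np.array([[0, 0.5], [0.5, 0]])
        assert average_linkage_cluster(d, 0.1) == [{0}, {1}]

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            average_linkage_cluster(d, 0.1)

    def test_single_item(self):
        assert average_linkage_cluster(np.zeros((1, 1)), 0.5) == [{0}]


@pytest.fixture(scope="module")
def small_scenario():
    return synthdata.simulate_catalog_bins(
        n_ancestors=2, bins_per_ancestor=5, length=60_000, seed=23
    )


class TestTwoStepClustering:
    def test_recovers_planted_clusters(self, small_scenario):
        bins, truth = small_scenario
        clusters = two_step_species_clustering(bins, s=1000)
        assert len(clusters) == 2
        got = {frozenset(c.members) for c in clusters}
        expected = {
            frozenset(b for b in truth.cluster_of if truth.cluster_of[b] == anc)
            for anc in set(truth.cluster_of.values())
        }
        assert got == expected
        assert all(c.iteration_found <= 2 for c in clusters)

    def test_single_bin_singleton(self, ancestors_50k):
        b = GenomeBin(bin_id="solo", contigs=[ancestors_50k[0]])
        clusters = two_step_species_clustering([b], s=500)
        assert len(clusters) == 1
        assert clusters[0].members == {"solo"}
        assert clusters[0].representative == "solo"

    def test_representative_is_highest_intactness(self, ancestors_50k):
        g = ancestors_50k[0]
        intact = GenomeBin(bin_id="intact", contigs=[g], completeness=95.0)
        # same sequence content but fragmented -> lower N50 -> lower S
        k = len(g) // 10
        shattered = GenomeBin(
            bin_id="shattered",
            contigs=[g[i * k : (i + 1) * k] for i in range(10)],
            completeness=95.0,
        )
        clusters = two_step_species_clustering([shattered, intact], s=500)
        assert len(clusters) == 1
        assert clusters[0].representative == "intact"

    def test_fixpoint_on_own_representatives(self, small_scenario):
        bins, _ = small_scenario
        by_id = {b.bin_id: b for b in bins}
        clusters = two_step_species_clustering(bins, s=1000)
        reps = [by_id[c.representative] for c in clusters]
        reclustered = two_step_species_clustering(reps, s=1000)
        assert {frozenset(c.members) for c in reclustered} == {
            frozenset({c.representative}) for c in clusters
        }

    def test_representative_permutation_invariant(self, small_scenario):
        bins, _ = small_scenario
        fwd = two_step_species_clustering(bins, s=1000)
        rev = two_step_species_clustering(bins[::-1], s=1000)
        assert {(frozenset(c.members), c.representative) for c in fwd} == {
            (frozenset(c.members), c.representative) for c in rev
        }


class TestMergeCatalog:
    def test_empty_new_all_inherited(self, ancestors_50k):
        base = [
            GenomeBin(bin_id=f"base{i}", contigs=[a]) for i, a in enumerate(ancestors_50k)
        ]
        clusters, prov = merge_catalog(base, [], s=500)
        assert set(prov["status"]) == {"inherited"}
        assert len(clusters) == 2

    def test_replaced_and_novel(self, ancestors_50k):
        g = ancestors_50k[0]
        base = [GenomeBin(bin_id="base0", contigs=[g], completeness=80.0)]
        near, _ = synthdata.evolve_genome(g, 0.01, seed=3)
        new = [
            GenomeBin(bin_id="new_hi", contigs=[near], completeness=99.0),
            GenomeBin(bin_id="new_far", contigs=[ancestors_50k[1]]),
        ]
        clusters, prov = merge_catalog(base, new, s=500)
        status = dict(zip(prov["representative"], prov["status"]))
        assert status["new_hi"] == "replaced"
        assert status["new_far"] == "novel"

    def test_id_collision_rejected(self, ancestors_50k):
        a = GenomeBin(bin_id="x", contigs=[ancestors_50k[0]])
        with pytest.raises(ValueError):
            merge_catalog([a], [a])


class TestNonRedundant:
    def test_identical_genomes_collapse(self, ancestors_50k):
        g = ancestors_50k[0]
        bins = [
            GenomeBin(bin_id=f"b{i}", contigs=[g], sample_id=f"s{i}") for i in range(3)
        ]
        species = {b.bin_id: "sp0" for b in bins}
        assert count_nonredundant(bins, species, s=500) == 1

    def test_same_sample_rule(self, ancestors_50k):
        g = ancestors_50k[0]
        g2, _ = synthdata.evolve_genome(g, 0.05, seed=9)  # mash d ~ 0.05
        same = [
            GenomeBin(bin_id="a", contigs=[g], sample_id="s1"),
            GenomeBin(bin_id="b", contigs=[g2], sample_id="s1"),
        ]
        species = {"a": "sp0", "b": "sp0"}
        assert count_nonredundant(same, species, s=500) == 1
        diff = [
            GenomeBin(bin_id="a", contigs=[g], sample_id="s1"),
            GenomeBin(bin_id="b", contigs=[g2], sample_id="s2"),
        ]
        assert count_nonredundant(diff, species, s=500) == 2


class TestCountrySpecific:
    @staticmethod
    def _cluster(i, members, rep=None):
        return SpeciesCluster(
            members=frozenset(members), representative=rep or sorted(members)[0]
        )

    def test_specificity_rules(self):
        clusters = [
            self._cluster(0, {"k1", "k2"}),
            self._cluster(1, {"k3", "j1"}),
            self._cluster(2, {"j2", "base9"}),
        ]
        country = {"k1": "Korea", "k2": "Korea", "k3": "Korea", "j1": "Japan", "j2": "Japan", "base9": "Japan"}
        specific, _ = country_specific_species(clusters, country, base_ids={"base9"})
        assert specific == {"Korea": [0]}

    def test_family_enrichment_detects_planted_excess(self):
        rng = np.random.default_rng(5)
        clusters = []
        family_of = {}
        country_of = {}
        for i in range(100):
            specific = i < 20
            bid = f"m{i}"
            clusters.append(self._cluster(i, {bid}))
            country_of[bid] = "Korea" if specific else ("Korea" if rng.random() < 0.5 else "Japan")
            if specific:
                family_of[i] = "F_hot" if rng.random() < 0.8 else "F_bg"
            else:
                family_of[i] = "F_hot" if rng.random() < 0.2 else "F_bg"
        base_ids = {f"m{i}" for i in range(20, 100)}  # rest counted as base
        specific, enrich = country_specific_species(clusters, country_of, base_ids, family_of)
        row = enrich.set_index("family").loc["F_hot"]
        assert row["odds_ratio"] > 1
        assert row["p_value"] < 0.05


@pytest.fixture(scope="module")
def depth_bins():
    rng = np.random.default_rng(8)
    ancestors = synthdata.generate_ancestors(30, 10_000, seed=88)
    low, high = [], []
    for i, anc in enumerate(ancestors):
        near, _ = synthdata.evolve_genome(anc, 0.01, seed=int(rng.integers(2**31)))
        low.append(
            GenomeBin(
                bin_id=f"low{i}", contigs=[anc],
                completeness=float(np.clip(rng.normal(78, 3), 50, 100)),
            )
        )
        high.append(
            GenomeBin(
                bin_id=f"high{i}", contigs=[near],
                completeness=float(np.clip(rng.normal(88, 3), 50, 100)),
            )
        )
    return low, high


class TestDepthPairing:
    def test_planted_quality_shift_detected(self, depth_bins):
        low, high = depth_bins
        table, tests = pair_conspecific_across_depths(low, high, s=300)
        assert len(table) == 30
        assert (table["low_id"].str[3:] == table["high_id"].str[4:]).all()
        assert tests["completeness"][1] < 0.05

    def test_identical_lists_all_zero_differences(self, depth_bins):
        low, _ = depth_bins
        copies = [
            GenomeBin(bin_id=f"c{i}", contigs=b.contigs, completeness=b.completeness)
            for i, b in enumerate(low)
        ]
        table, tests = pair_conspecific_across_depths(low, copies, s=300)
        assert (table["completeness_low"] == table["completeness_high"]).all()
        assert tests["n50"][1] == 1.0

    def test_ambiguous_clusters_excluded(self, depth_bins):
        low, high = depth_bins
        extra = GenomeBin(bin_id="low_dup", contigs=low[0].contigs, completeness=70.0)
        table, _ = pair_conspecific_across_depths(low + [extra], high, s=300)
        # the duplicated low-depth species is rejected from pairing
        assert len(table) == 29
        assert "low0" not in set(table["low_id"])

    def test_no_pairs_is_error(self, ancestors_50k):
        a = GenomeBin(bin_id="a", contigs=[ancestors_50k[0]])
        b = GenomeBin(bin_id="b", contigs=[ancestors_50k[1]])
        with pytest.raises(ValueError):
            pair_conspecific_across_depths([a], [b], s=300)
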