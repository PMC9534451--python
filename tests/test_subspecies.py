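import itertools

import numpy as np
import pytest

from microcensus import (
    SnvProfile,
    aggregate_profiles,
    diversity_vs_population,
    nucleotide_diversity,
    polymorphic_sites,
    synth_snv_population,
)


def _profile(counts, species="sp", gene_ids=None):
    counts = np.asarray(counts)
    if counts.ndim == 2:
        counts = counts[None, :, :]
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    return SnvProfile(species=species, gene_ids=gene_ids, counts=counts)


class TestNucleotideDiversity:
    def test_monomorphic_site_has_zero_heterozygosity(self):
        profile = _profile([[10, 0, 0, 0]])
        assert nucleotide_diversity(profile).pi == 0.0

    def test_hand_case_point_one(self):
        # one site with alleles 1/1 (h = (2/1) * (1 - 0.5) = 1), nine
        # monomorphic covered sites -> gene pi = 1/10
        counts = np.zeros((10, 4), dtype=int)
        counts[0] = [1, 1, 0, 0]
        counts[1:, 0] = 2
        profile = _profile(counts)
        assert nucleotide_diversity(profile).pi == pytest.approx(0.1)

    def test_matches_brute_force_pairwise_differences(self):
        # two explicit haplotypes pooled at equal depth: pi at each site
        # should equal the average pairwise difference between reads,
        # enumerated exhaustively
        hap1 = [0, 1, 2, 3, 0]
        hap2 = [0, 1, 3, 3, 1]
        depth = 4  # 4 reads of each haplotype
        counts = np.zeros((5, 4), dtype=int)
        for s in range(5):
            counts[s, hap1[s]] += depth
            counts[s, hap2[s]] += depth
        profile = _profile(counts)
        reads = [hap1] * depth + [hap2] * depth
        per_site_diffs = []
        for s in range(5):
            alleles = [r[s] for r in reads]
            pairs = list(itertools.combinations(alleles, 2))
            per_site_diffs.append(
                sum(a != b for a, b in pairs) / len(pairs)
            )
        assert nucleotide_diversity(profile).pi == pytest.approx(
            np.mean(per_site_diffs)
        )

    def test_invariant_to_allele_relabeling(self):
        counts = np.array([[6, 2, 0, 0], [3, 3, 2, 0]])
        relabeled = counts[:, [2, 0, 3, 1]]
        assert nucleotide_diversity(_profile(counts)).pi == pytest.approx(
            nucleotide_diversity(_profile(relabeled)).pi
        )

    def test_no_covered_site_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            nucleotide_diversity(_profile([[1, 0, 0, 0]]), min_depth=2)


class TestPolymorphicSites:
    def test_all_monomorphic_is_zero(self):
        assert polymorphic_sites(_profile([[9, 0, 0, 0], [0, 4, 0, 0]])) == 0

    def test_single_biallelic_site(self):
        assert polymorphic_sites(_profile([[5, 3, 0, 0], [9, 0, 0, 0]])) == 1

    def test_invariant_to_depth_scaling(self):
        counts = np.array([[6, 2, 0, 0], [3, 0, 0, 0], [1, 1, 1, 1]])
        assert polymorphic_sites(_profile(counts)) == polymorphic_sites(
            _profile(counts * 10)
        )

    def test_non_decreasing_under_aggregation(self):
        # exhaustive over all subsets of four synthetic hosts
        pop = synth_snv_population(
            hosts=4, genes=2, sites_per_gene=20, haplotype_pool_size=3, seed=5
        )
        for r in range(1, 4):
            for subset in itertools.combinations(range(4), r):
                for extra in set(range(4)) - set(subset):
                    small = aggregate_profiles([pop.profiles[i] for i in subset])
                    big = aggregate_profiles(
                        [pop.profiles[i] for i in (*subset, extra)]
                    )
                    assert polymorphic_sites(big) >= polymorphic_sites(small)


class TestAggregateProfiles:
    def test_single_profile_identity(self):
        p = _profile([[5, 3, 0, 0]])
        agg = aggregate_profiles([p])
        np.testing.assert_array_equal(agg.counts, p.counts)

    def test_depths_add(self):
        a = _profile([[5, 0, 0, 0]])
        b = _profile([[2, 3, 0, 0]])
        agg = aggregate_profiles([a, b])
        np.testing.assert_array_equal(agg.depths, a.depths + b.depths)

    def test_two_fixed_hosts_make_polymorphism(self):
        a = _profile([[8, 0, 0, 0]])
        b = _profile([[0, 8, 0, 0]])
        assert polymorphic_sites(a) == polymorphic_sites(b) == 0
        assert polymorphic_sites(aggregate_profiles([a, b])) == 1

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="species"):
            aggregate_profiles(
                [_profile([[1, 1, 0, 0]], "x"), _profile([[1, 1, 0, 0]], "y")]
            )


@pytest.fixture(scope="module")
def population():
    return synth_snv_population(
        hosts=12, genes=4, sites_per_gene=50, haplotype_pool_size=5,
        depth=30, seed=8,
    )


class TestDiversityVsPopulation:
    def test_full_size_has_zero_sd(self, population):
        curve, _ = diversity_vs_population(
            population.profiles, sizes=(12,), reps=10, seed=9
        )
        assert curve.iloc[0]["pi_sd"] == 0.0
        assert curve.iloc[0]["polymorphic_sd"] == 0.0

    def test_polymorphic_count_grows_to_pool_implied_saturation(self, population):
        curve, _ = diversity_vs_population(
            population.profiles, sizes=(1, 3, 12), reps=20, seed=10
        )
        means = curve.set_index("size")["polymorphic_mean"]
        assert means[1] < means[3] <= means[12]
        # at the full population the count equals the exhaustive
        # haplotype-difference enumeration (noise-free generator)
        assert means[12] == population.pool_polymorphic_sites()

    def test_pooled_pi_exceeds_single_host_pi(self, population):
        curve, _ = diversity_vs_population(
            population.profiles, sizes=(1, 12), reps=20, seed=11
        )
        pis = curve.set_index("size")["pi_mean"]
        assert pis[1] <= pis[12]

    def test_size_exceeding_hosts_rejected(self, population):
        with pytest.raises(ValueError, match="exceeds"):
            diversity_vs_population(population.profiles, sizes=(13,))

    def test_tsv_round_trip(self, population, tmp_path):
        p = population.profiles[0]
        path = tmp_path / "snv.tsv"
        p.to_tsv(path)
        again = SnvProfile.from_tsv(path)
        assert again.species == p.species
        assert again.gene_ids == p.gene_ids
        np.testing.assert_array_equal(again.counts, p.counts)
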