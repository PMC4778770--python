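import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from commnull.core import UndefinedMetricError
from commnull.matrix import CommunityMatrix, TraitVector
from commnull.traits import (aits_shuffle, awts_shuffle, community_trait_metrics,
                             site_nn_stats, trait_null_distribution)


def _one_site_matrix(m):
    return CommunityMatrix(np.ones((m, 1), dtype=np.uint8))


class TestSiteStats:
    def test_hand_computed_example(self, single_site_traits):
        matrix, traits = single_site_traits
        s = site_nn_stats(matrix, traits, 0)
        # traits {1,2,4}: nearest-neighbour distances {1,1,2}
        assert s.nn_mean == pytest.approx(4 / 3)
        assert s.nn_sd == pytest.approx(0.57735, abs=1e-5)
        assert s.species_in_site == 3

    def test_tied_traits_give_zero_distances(self):
        matrix = _one_site_matrix(2)
        s = site_nn_stats(matrix, TraitVector(np.array([5.0, 5.0])), 0)
        assert s.nn_mean == 0.0 and s.nn_sd == 0.0

    def test_single_species_site_undefined(self):
        occ = np.array([[1, 1], [0, 1]], dtype=np.uint8)
        s = site_nn_stats(CommunityMatrix(occ), TraitVector(np.array([1.0, 2.0])), 0)
        assert s.nn_mean is None and s.nn_sd is None


class TestCommunityMetrics:
    def test_single_site_community(self, single_site_traits):
        matrix, traits = single_site_traits
        nn, sdnn = community_trait_metrics(matrix, traits)
        assert nn == pytest.approx(4 / 3)
        assert sdnn == pytest.approx(0.57735, abs=1e-5)

    def test_identical_traits_zero(self):
        nn, sdnn = community_trait_metrics(_one_site_matrix(4),
                                           TraitVector(np.full(4, 7.0)))
        assert nn == 0.0 and sdnn == 0.0

    def test_duplicated_sites_equal_single_site(self, single_site_traits):
        matrix, traits = single_site_traits
        doubled = CommunityMatrix(np.ones((3, 2), dtype=np.uint8))
        assert community_trait_metrics(doubled, traits) == pytest.approx(
            community_trait_metrics(matrix, traits))

    def test_order_invariance(self, rng):
        occ = (rng.random((6, 8)) < 0.6).astype(np.uint8)
        occ[occ.sum(1) == 0] = 1
        occ[:, occ.sum(0) == 0] = 1
        matrix = CommunityMatrix(occ)
        traits = TraitVector(rng.uniform(0, 100, 6))
        base = community_trait_metrics(matrix, traits)
        perm = rng.permutation(6)
        shuffled = CommunityMatrix(occ[perm][:, rng.permutation(8)])
        assert community_trait_metrics(
            shuffled, TraitVector(traits.values[perm])) == pytest.approx(base)

    def test_all_singleton_sites_undefined(self):
        with pytest.raises(UndefinedMetricError):
            community_trait_metrics(CommunityMatrix(np.eye(3, dtype=np.uint8)),
                                    TraitVector(np.array([1.0, 2.0, 3.0])))


class TestShuffles:
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_multiset_preserved_by_both_schemes(self, values, seed):
        traits = TraitVector(np.array(values))
        rng = np.random.default_rng(seed)
        occurrences = rng.integers(1, 10, len(values))
        a = aits_shuffle(traits, rng)
        w = awts_shuffle(traits, occurrences, rng)
        assert np.array_equal(np.sort(a.values), np.sort(traits.values))
        assert np.array_equal(np.sort(w.values), np.sort(traits.values))

    def test_aits_uniform_over_permutations(self):
        traits = TraitVector(np.array([1.0, 2.0, 3.0]))
        rng = np.random.default_rng(17)
        counts = {}
        reps = 60_000
        for _ in range(reps):
            out = tuple(aits_shuffle(traits, rng).values)
            counts[out] = counts.get(out, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - reps / 6) ** 2 / (reps / 6) for c in counts.values())
        assert stats.chi2.sf(chi2, 5) > 1e-3

    def test_awts_equal_occurrences_matches_aits(self):
        """With equal occurrence counts the weighted deal collapses to a
        uniform permutation (chi-square over all 6 orders of 3 species)."""
        traits = TraitVector(np.array([1.0, 2.0, 3.0]))
        occurrences = np.array([4, 4, 4])
        rng = np.random.default_rng(23)
        counts = {}
        reps = 60_000
        for _ in range(reps):
            out = tuple(awts_shuffle(traits, occurrences, rng).values)
            counts[out] = counts.get(out, 0) + 1
        assert len(counts) == 6
        chi2 = sum((c - reps / 6) ** 2 / (reps / 6) for c in counts.values())
        assert stats.chi2.sf(chi2, 5) > 0.01

    def test_awts_aligns_values_with_abundance(self):
        # strongly skewed occurrences: the most abundant species should
        # receive the largest trait value far more often than 1/m
        traits = TraitVector(np.array([10.0, 20.0, 30.0, 40.0]))
        occurrences = np.array([100, 1, 1, 1])
        rng = np.random.default_rng(5)
        hits = sum(awts_shuffle(traits, occurrences, rng).values[0] == 40.0
                   for _ in range(2000))
        assert hits / 2000 > 0.9

    def test_validation(self):
        traits = TraitVector(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            awts_shuffle(traits, np.array([1, 0]), np.random.default_rng(0))
        with pytest.raises(ValueError):
            awts_shuffle(traits, np.array([1, 1, 1]), np.random.default_rng(0))


class TestTraitNull:
    def test_identical_traits_degenerate_null(self, rng):
        matrix = _one_site_matrix(4)
        traits = TraitVector(np.full(4, 3.0))
        dist = trait_null_distribution(matrix, traits, "nn", "aits", 100, rng)
        assert np.all(dist.null_values == dist.observed)

    def test_aits_null_matches_exhaustive_enumeration(self, rng):
        """3 species in one site: the null must match the exact distribution
        of NN over the 6 trait permutations."""
        matrix = _one_site_matrix(3)
        traits = TraitVector(np.array([1.0, 2.0, 4.0]))
        exact = []
        for p in itertools.permutations(traits.values):
            order = np.sort(np.array(p))
            d = [order[1] - order[0], min(order[1] - order[0], order[2] - order[1]),
                 order[2] - order[1]]
            exact.append(np.mean(d))
        dist = trait_null_distribution(matrix, traits, "nn", "aits", 2000, rng)
        # single-site NN is permutation-invariant here: all 6 values coincide
        assert set(np.round(dist.null_values, 12)) <= set(np.round(exact, 12))
        assert dist.observed == pytest.approx(4 / 3)

    @pytest.mark.parametrize("metric,scheme", [("nn", "aits"), ("sdnn", "aits"),
                                               ("nn", "awts"), ("sdnn", "awts")])
    def test_reproducible_and_multiset_safe(self, small_matrix, metric, scheme):
        traits = TraitVector(np.array([3.0, 1.5, 9.0, 4.25]))
        a = trait_null_distribution(small_matrix, traits, metric, scheme, 50,
                                    np.random.default_rng(2))
        b = trait_null_distribution(small_matrix, traits, metric, scheme, 50,
                                    np.random.default_rng(2))
        assert np.array_equal(a.null_values, b.null_values)

    def test_unknown_metric_or_scheme(self, small_matrix):
        traits = TraitVector(np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            trait_null_distribution(small_matrix, traits, metric="mpd")
        with pytest.raises(ValueError):
            trait_null_distribution(small_matrix, traits, scheme="independent")
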