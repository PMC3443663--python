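import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from miract.comparisons import (DeregulationProfile, cluster_average_linkage,
                                correlation_distance, dendrogram_newick,
                                overlap_test, ras_switching, read_profile,
                                subtype_specific, threshold_pathway,
                                welch_one_tailed)
from miract.io import FormatError, PathwayProbabilities
from miract.validation import hypergeom_tail_exact


def profile(label, act, sil, universe):
    return DeregulationProfile(label, frozenset(act), frozenset(sil),
                               frozenset(universe))


UNIVERSE = [f"m{i}" for i in range(10)]


class TestOverlapTest:
    def test_complete_overlap_extreme(self):
        u = [f"m{i}" for i in range(20)]
        a = u[:5]
        k, p = overlap_test(a, a, u)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(20, 5))

    def test_minimum_possible_overlap_gives_one(self):
        u = [f"m{i}" for i in range(12)]
        k, p = overlap_test(u[:5], u[5:10], u)
        assert k == 0 and p == 1.0

    def test_matches_exact_tail_sum(self):
        rng = np.random.default_rng(0)
        u = [f"m{i}" for i in range(100)]
        a = set(rng.choice(u, 42, replace=False))
        b = set(rng.choice(u, 30, replace=False))
        k, p = overlap_test(a, b, u)
        assert p == pytest.approx(hypergeom_tail_exact(k, 100, 42, 30),
                                  rel=1e-10)

    def test_exhaustive_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 31))
            u = [f"m{i}" for i in range(n)]
            a = set(rng.choice(u, int(rng.integers(0, n + 1)), replace=False))
            b = set(rng.choice(u, int(rng.integers(0, n + 1)), replace=False))
            k, p = overlap_test(a, b, u)
            assert p == pytest.approx(
                hypergeom_tail_exact(k, n, len(a), len(b)), rel=1e-10)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test({"zz"}, set(), UNIVERSE)


class TestSubtypeSpecific:
    def test_unique_to_one_condition(self):
        p1 = profile("LEIO", {"m1"}, set(), UNIVERSE)
        p2 = profile("SYN", set(), set(), UNIVERSE)
        unique = subtype_specific([p1, p2])
        assert unique["LEIO"]["activated"] == {"m1"}
        assert unique["SYN"]["activated"] == set()

    def test_shared_mirna_in_no_unique_list(self):
        p1 = profile("A", {"m1"}, set(), UNIVERSE)
        p2 = profile("B", {"m1", "m2"}, set(), UNIVERSE)
        unique = subtype_specific([p1, p2])
        assert "m1" not in unique["A"]["activated"]
        assert unique["B"]["activated"] == {"m2"}

    def test_three_profiles_hand_enumerated(self):
        p1 = profile("A", {"m1", "m2"}, {"m7"}, UNIVERSE)
        p2 = profile("B", {"m2", "m3"}, {"m7", "m8"}, UNIVERSE)
        p3 = profile("C", {"m4"}, {"m9"}, UNIVERSE)
        unique = subtype_specific([p1, p2, p3])
        assert unique["A"] == {"activated": {"m1"}, "silenced": set()}
        assert unique["B"] == {"activated": {"m3"}, "silenced": {"m8"}}
        assert unique["C"] == {"activated": {"m4"}, "silenced": {"m9"}}

    def test_unique_sets_pairwise_disjoint(self):
        rng = np.random.default_rng(2)
        profiles = []
        for i in range(4):
            act = set(rng.choice(UNIVERSE, 4, replace=False))
            sil = set(rng.choice(sorted(set(UNIVERSE) - act), 2,
                                 replace=False))
            profiles.append(profile(f"c{i}", act, sil, UNIVERSE))
        unique = subtype_specific(profiles)
        labels = list(unique)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                for d in ("activated", "silenced"):
                    assert not (unique[labels[i]][d] & unique[labels[j]][d])

    def test_differing_universes_rejected(self):
        p1 = profile("A", set(), set(), UNIVERSE)
        p2 = profile("B", set(), set(), UNIVERSE[:5])
        with pytest.raises(ValueError, match="universe"):
            subtype_specific([p1, p2])


class TestRasSwitching:
    def test_intersection(self):
        pa = profile("on", {"m1", "m2", "m3"}, set(), UNIVERSE)
        pi = profile("off", set(), {"m2", "m3", "m4"}, UNIVERSE)
        switching, k, _ = ras_switching(pa, pi)
        assert switching == {"m2", "m3"} and k == 2

    def test_disjoint_lists_give_empty_set(self):
        pa = profile("on", {"m1"}, set(), UNIVERSE)
        pi = profile("off", set(), {"m2"}, UNIVERSE)
        switching, _, p = ras_switching(pa, pi)
        assert switching == set()
        assert p == 1.0

    def test_subset_of_both_input_lists(self):
        rng = np.random.default_rng(3)
        act = set(rng.choice(UNIVERSE, 5, replace=False))
        sil = set(rng.choice(UNIVERSE, 5, replace=False))
        pa = profile("on", act, set(), UNIVERSE)
        pi = profile("off", set(), sil, UNIVERSE)
        switching, _, _ = ras_switching(pa, pi)
        assert switching <= act and switching <= sil


class TestThresholdPathway:
    def test_below_cutoff_excluded(self):
        probs = PathwayProbabilities({"s1": 0.9, "s2": 0.79})
        active, inactive = threshold_pathway(probs, 0.8)
        assert active == ["s1"] and inactive == ["s2"]

    def test_cutoff_is_inclusive_minimum(self):
        probs = PathwayProbabilities({"s1": 0.8})
        active, _ = threshold_pathway(probs, 0.8)
        assert active == ["s1"]

    def test_no_active_samples_warns(self):
        probs = PathwayProbabilities({"s1": 0.1, "s2": 0.2})
        with pytest.warns(UserWarning, match="cutoff"):
            active, inactive = threshold_pathway(probs, 0.8)
        assert active == [] and set(inactive) == {"s1", "s2"}


class TestWelchOneTailed:
    def test_textbook_example(self):
        t, df, p = welch_one_tailed([1, 2, 3], [3, 4, 5])
        assert t == pytest.approx(-2.449489742783178)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.03523, abs=5e-5)

    def test_identical_groups_give_half(self):
        t, _, p = welch_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_constant_equal_groups_half_by_convention(self):
        with pytest.warns(UserWarning, match="convention"):
            _, _, p = welch_one_tailed([2.0, 2.0], [2.0, 2.0])
        assert p == 0.5

    def test_large_gap_is_significant(self):
        _, _, p = welch_one_tailed([0.0, 0.1, 0.2, 0.05],
                                   [10.0, 10.1, 10.2, 10.05])
        assert p < 1e-4

    def test_direction_matters(self):
        _, _, p_less = welch_one_tailed([1, 2, 3], [5, 6, 7],
                                        "a_less_than_b")
        _, _, p_greater = welch_one_tailed([1, 2, 3], [5, 6, 7],
                                           "a_greater_than_b")
        assert p_less < 0.05 < p_greater


class TestClustering:
    def test_three_item_hand_example(self):
        d = np.array([[0.0, 1.0, 4.0],
                      [1.0, 0.0, 5.0],
                      [4.0, 5.0, 0.0]])
        merges = cluster_average_linkage(d, distance="precomputed")
        assert (merges[0].left, merges[0].right) == (0, 1)
        assert merges[0].height == 1.0
        assert merges[1].height == pytest.approx(4.5)

    def test_two_items_single_merge(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        merges = cluster_average_linkage(d, distance="precomputed")
        assert len(merges) == 1 and merges[0].height == 2.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.5, 10, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        merges = cluster_average_linkage(d, distance="precomputed")
        Z = linkage(squareform(d, checks=False), method="average")
        for m, row in zip(merges, Z):
            assert {m.left, m.right} == {int(row[0]), int(row[1])}
            assert m.height == pytest.approx(row[2])

    def test_zero_variance_item_named(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                           [3.0, 1.0, 2.0]], index=["flat", "a", "b"])
        with pytest.raises(FormatError, match="flat"):
            correlation_distance(df)

    def test_correlation_distance_clusters_correlated_rows(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 12)
        df = pd.DataFrame(
            [base + rng.normal(0, 0.05, 12),
             base + rng.normal(0, 0.05, 12),
             rng.normal(0, 1, 12)],
            index=["a", "b", "c"])
        merges = cluster_average_linkage(df)
        assert {merges[0].left, merges[0].right} == {0, 1}

    def test_newick_output(self):
        d = np.array([[0.0, 1.0, 4.0],
                      [1.0, 0.0, 5.0],
                      [4.0, 5.0, 0.0]])
        merges = cluster_average_linkage(d, distance="precomputed")
        nwk = dendrogram_newick(merges, ["A", "B", "C"])
        assert nwk.endswith(";")
        assert "A:0.5" in nwk and "B:0.5" in nwk and "C:2.25" in nwk


class TestProfileIO:
    def test_round_trip(self, tmp_path):
        p = profile("LEIO vs normal", {"m1"}, {"m2"}, UNIVERSE)
        p.write(tmp_path / "p.tsv", ["seed=1"])
        back = read_profile(tmp_path / "p.tsv")
        assert back == p

    def test_conflicting_calls_rejected(self):
        with pytest.raises(ValueError, match="both"):
            profile("x", {"m1"}, {"m1"}, UNIVERSE)
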