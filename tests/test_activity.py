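import numpy as np
import pandas as pd
import pytest

from miract.activity import (MiRNAActivityModel, activity_score,
                             call_deregulated, empirical_p, estimate_fdr,
                             permutation_null)
from miract.io import TargetSetCollection
from miract.synthetic import SimulationSpec, generate_expression
from miract.validation import activity_score_brute_force, fdr_brute_force

from conftest import vector_with_ranks


class TestActivityScore:
    def test_targets_at_top_score_negative(self, ten_gene_vector):
        # targets at ranks 1,2: running sum peaks at +4 -> AS = -4 (silenced)
        assert activity_score(ten_gene_vector, {"g00", "g01"}) == -4.0

    def test_targets_at_bottom_score_positive(self, ten_gene_vector):
        assert activity_score(ten_gene_vector, {"g08", "g09"}) == 4.0

    def test_magnitude_tie_resolved_to_smallest_rank(self, ten_gene_vector):
        # targets at ranks 5,6: extrema -2 (rank 4) and +2 (rank 6);
        # smallest rank wins -> D = -2 -> AS = +2
        assert activity_score(ten_gene_vector, {"g04", "g05"}) == 2.0

    def test_disjoint_target_set_rejected(self, ten_gene_vector):
        with pytest.raises(ValueError, match="intersect"):
            activity_score(ten_gene_vector, {"absent"})

    def test_all_genes_targets_degenerate(self, ten_gene_vector):
        with pytest.raises(ValueError):
            activity_score(ten_gene_vector, set(ten_gene_vector.genes))

    def test_genes_off_vector_ignored(self, ten_gene_vector):
        a = activity_score(ten_gene_vector, {"g08", "g09"})
        b = activity_score(ten_gene_vector, {"g08", "g09", "absent"})
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_plain_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        m = int(rng.integers(1, n))
        ranks = rng.choice(n, m, replace=False)
        v = vector_with_ranks(n)
        got = activity_score(v, {v.genes[r] for r in ranks})
        assert got == pytest.approx(activity_score_brute_force(ranks, n))

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetry_under_vector_reversal(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = vector_with_ranks(15)
        targets = set(rng.choice(v.genes, 4, replace=False))
        fwd = activity_score(v, targets)
        rev = activity_score(v.reversed(), targets)
        assert rev == pytest.approx(-fwd)

    def test_depends_only_on_ranks(self):
        from miract.preprocess import ExpressionChangeVector
        genes = [f"g{i:02d}" for i in range(8)]
        a = ExpressionChangeVector(genes, np.arange(8, 0, -1, dtype=float),
                                   "case", "normal")
        b = ExpressionChangeVector(genes, np.exp(-np.arange(8.0)),
                                   "case", "normal")
        targets = {"g01", "g05", "g06"}
        assert activity_score(a, targets) == activity_score(b, targets)


class TestPermutationNull:
    def test_reproducible_for_fixed_seed(self, small_matrix):
        targets = TargetSetCollection({"m1": frozenset({"G1", "G3"}),
                                       "m2": frozenset({"G2"})})
        a = permutation_null(small_matrix, "case", "normal", targets,
                            K=20, seed=11)
        b = permutation_null(small_matrix, "case", "normal", targets,
                            K=20, seed=11)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_different_seeds_differ(self, small_matrix):
        targets = TargetSetCollection({"m1": frozenset({"G1", "G3"})})
        a = permutation_null(small_matrix, "case", "normal", targets,
                            K=20, seed=1)
        b = permutation_null(small_matrix, "case", "normal", targets,
                            K=20, seed=2)
        assert not np.array_equal(a.scores, b.scores)

    def test_null_scores_centred_on_null_data(self):
        spec = SimulationSpec(n_genes=300, n_mirnas=10, targets_per_mirna=20,
                              n_case=10, n_comparator=10, effect_size=0.0,
                              seed=3)
        matrix, targets, _ = generate_expression(spec)
        ns = permutation_null(matrix, "case", "normal", targets, K=200,
                              seed=3)
        # running-sum statistic is symmetric under the null; Monte-Carlo SEM
        sem = ns.scores.std(axis=1) / np.sqrt(ns.K)
        assert (np.abs(ns.scores.mean(axis=1)) < 4 * sem + 0.5).all()


class TestEmpiricalP:
    def test_no_exceedance_gives_pseudocount(self):
        assert empirical_p(5.0, np.zeros(3)) == pytest.approx(1 / 4)

    def test_zero_score_gives_one(self):
        assert empirical_p(0.0, np.array([1.0, -2.0, 0.5])) == 1.0

    def test_two_sided_exceedance_count(self):
        assert empirical_p(2.0, np.array([-3.0, 1.0, 2.0, -1.0])) \
            == pytest.approx(3 / 5)


class TestEstimateFdr:
    AS = np.array([2.0, 1.0])
    NS = np.array([[1.0, -1.0], [0.5, -0.5]])

    def test_ratio_at_threshold_one(self):
        assert estimate_fdr(self.AS, self.NS, 1.0) == pytest.approx(0.5)

    def test_ratio_at_threshold_two(self):
        assert estimate_fdr(self.AS, self.NS, 2.0) == 0.0

    def test_null_equal_observed_gives_one(self):
        obs = np.array([2.0, 1.0])
        ns = obs[:, None]  # identity permutation, K=1
        assert estimate_fdr(obs, ns, 1.0) == 1.0

    def test_empty_side_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert estimate_fdr(np.array([1.0]), np.array([[0.5]]), -1.0) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(0, 2, int(rng.integers(1, 11)))
        ns = rng.normal(0, 2, (len(obs), int(rng.integers(1, 21))))
        star = float(rng.normal(0, 2))
        assert estimate_fdr(obs, ns, star) == pytest.approx(
            fdr_brute_force(obs, ns, star), abs=1e-14)


class TestCalls:
    def frame(self, scores, p, fdr):
        return pd.DataFrame(
            {"as_score": scores, "p_value": p, "fdr": fdr},
            index=[f"m{i}" for i in range(len(scores))])

    def test_nothing_called_when_all_p_one(self):
        df = self.frame([3.0, -2.0], [1.0, 1.0], [0.0, 0.0])
        assert call_deregulated(df) == ([], [])

    def test_single_significant_activation(self):
        df = self.frame([3.0], [0.001], [0.005])
        assert call_deregulated(df, 0.005, 0.01) == (["m0"], [])

    def test_lists_sorted_by_absolute_score(self):
        df = self.frame([1.0, 3.0, -2.0], [0.001] * 3, [0.0] * 3)
        act, sil = call_deregulated(df)
        assert act == ["m1", "m0"] and sil == ["m2"]

    def test_stricter_fdr_gives_subset(self):
        rng = np.random.default_rng(8)
        df = self.frame(rng.normal(0, 2, 30), rng.uniform(0, 0.01, 30),
                        rng.uniform(0, 0.1, 30))
        strict_a, strict_s = call_deregulated(df, 0.005, 0.01)
        loose_a, loose_s = call_deregulated(df, 0.005, 0.05)
        assert set(strict_a) <= set(loose_a)
        assert set(strict_s) <= set(loose_s)

    def test_bad_threshold_rejected(self):
        df = self.frame([1.0], [0.5], [0.5])
        with pytest.raises(ValueError):
            call_deregulated(df, 0.0, 0.01)


@pytest.fixture(scope="module")
def fitted():
    spec = SimulationSpec.with_planted(
        2, 2, n_genes=400, n_mirnas=12, targets_per_mirna=25,
        n_case=10, n_comparator=10, seed=5)
    matrix, targets, truth = generate_expression(spec)
    model = MiRNAActivityModel(matrix, targets, "case", "normal")
    return model.fit(n_permutations=200, seed=5, fdr_threshold=0.05), truth


class TestModelFit:

    def test_result_invariants(self, fitted):
        res, _ = fitted
        df = res.results_
        assert (df["m_used"] >= 1).all()
        assert df["fdr"].between(0, 1).all()
        assert (df["p_value"] > 0).all() and (df["p_value"] <= 1).all()
        act = df[df["call"] == "activated"]
        sil = df[df["call"] == "silenced"]
        assert (act["as_score"] > 0).all()
        assert (sil["as_score"] < 0).all()

    def test_planted_mirnas_have_correct_sign(self, fitted):
        res, truth = fitted
        for mid, status in truth.status.items():
            if status == "activated":
                assert res.results_.at[mid, "as_score"] > 0
            elif status == "silenced":
                assert res.results_.at[mid, "as_score"] < 0

    def test_refit_is_deterministic(self, fitted):
        res, _ = fitted
        again = res.model.fit(n_permutations=200, seed=5,
                              fdr_threshold=0.05)
        pd.testing.assert_frame_equal(res.results_, again.results_)

    def test_summary_renders(self, fitted):
        res, _ = fitted
        text = str(res.summary())
        assert "miRNA" in text and "FDR" in text

    def test_profile_universe_is_scored_set(self, fitted):
        res, _ = fitted
        profile = res.to_profile("toy")
        assert profile.universe == frozenset(res.results_.index)
        assert profile.activated <= profile.universe

    def test_low_permutation_count_warns(self, fitted):
        res, _ = fitted
        with pytest.warns(UserWarning, match="low"):
            res.model.fit(n_permutations=50, seed=1)
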