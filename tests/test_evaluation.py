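import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from synforest import (
    GeneratorSpec,
    SyntheticConfig,
    brier_score,
    friedman_iman_davenport,
    replicate_benchmark,
    standardized_mse,
    summarize_benchmark,
    wilcoxon_signed_rank,
)
from synforest.evaluation import kfold_indices


class TestStandardizedMSE:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(30)
        assert standardized_mse(y, y) == 0.0

    def test_constant_mean_is_exactly_100(self, rng):
        y = rng.standard_normal(50)
        yhat = np.full(50, y.mean())
        assert standardized_mse(y, yhat) == pytest.approx(100.0, abs=1e-10)

    def test_hand_value(self):
        # MSE = 5/3, Var = 2/3 -> 250
        assert standardized_mse(
            np.array([0.0, 1.0, 2.0]), np.zeros(3)
        ) == pytest.approx(250.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardized_mse(np.ones(5), np.zeros(5))

    def test_external_variance(self, rng):
        y = rng.standard_normal(40)
        v = 2.5
        expected = 100 * np.mean(y**2) / v
        assert standardized_mse(y, np.zeros(40), var_y=v) == pytest.approx(expected)


class TestBrierScore:
    @pytest.mark.parametrize("J", [2, 3, 5])
    def test_uniform_guessing_scores_25(self, J, rng):
        n = 40
        probs = np.full((n, J), 1.0 / J)
        labels = rng.integers(0, J, n)
        assert brier_score(probs, labels) == pytest.approx(25.0, abs=1e-12)

    def test_perfect_one_hot_scores_0(self):
        labels = np.array([0, 2, 1, 2])
        probs = np.eye(3)[labels]
        assert brier_score(probs, labels) == 0.0

    def test_hand_value_j3(self):
        # (0.5,0.3,0.2) vs label 0: raw sum 0.38, * 3/8 * 100 = 14.25
        probs = np.array([[0.5, 0.3, 0.2]])
        assert brier_score(probs, np.array([0])) == pytest.approx(14.25)

    def test_nonstochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            brier_score(np.array([[0.5, 0.6]]), np.array([0]))

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            brier_score(np.array([[0.5, 0.5]]), np.array([2]))


class TestKFold:
    def test_partition_is_exact(self):
        folds = kfold_indices(53, 10, seed=4)
        flat = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(flat, np.arange(53))
        sizes = [f.size for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_seeded_folds_reproducible(self):
        a = kfold_indices(40, 5, seed=9)
        b = kfold_indices(40, 5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_stratified_folds_cover_classes(self):
        labels = np.repeat([0, 1, 2], 20)
        folds = kfold_indices(60, 5, seed=1, labels=labels)
        for f in folds:
            assert set(labels[f]) == {0, 1, 2}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 10, seed=0)

    def test_constant_predictor_scores_100_under_cv(self, rng):
        # pooled out-of-fold predictions from per-fold training means
        y = rng.standard_normal(60)
        pooled = np.empty(60)
        for f in kfold_indices(60, 10, seed=2):
            mask = np.ones(60, dtype=bool)
            mask[f] = False
            pooled[f] = y[mask].mean()
        val = standardized_mse(y, pooled, var_y=float(np.var(y)))
        assert val == pytest.approx(100.0, rel=0.05)


def wilcoxon_enumeration_oracle(diffs):
    """Exhaustive two-sided p: enumerate all sign patterns on |d| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            np.sum(ranks[list(signs)])
            for signs in itertools.product(
                [False, True], repeat=len(ranks)
            )
        ]
    )
    tol = 1e-9
    p_ge = np.mean(ws >= w_obs - tol)
    p_le = np.mean(ws <= w_obs + tol)
    return w_obs, min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_positive_three(self):
        w, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_antisymmetry(self, rng):
        d = rng.standard_normal(15)
        _, p_pos = wilcoxon_signed_rank(d)
        _, p_neg = wilcoxon_signed_rank(-d)
        assert p_pos == pytest.approx(p_neg, abs=1e-12)

    def test_zeros_dropped(self):
        w1, p1 = wilcoxon_signed_rank(np.array([0.0, 1.0, 2.0, 3.0, 0.0]))
        w2, p2 = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert (w1, p1) == (w2, p2)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            w, p = wilcoxon_signed_rank(np.zeros(4))
        assert p == 1.0

    @pytest.mark.parametrize("n", range(1, 13))
    def test_exact_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = np.round(rng.standard_normal(n), 1)  # rounding induces ties
        d[d == 0] = 0.5
        w_exp, p_exp = wilcoxon_enumeration_oracle(d)
        w, p = wilcoxon_signed_rank(d)
        assert w == pytest.approx(w_exp)
        assert p == pytest.approx(p_exp, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=-40, max_value=40).filter(lambda v: v != 0),
            min_size=1,
            max_size=10,
        )
    )
    def test_exact_matches_enumeration_property(self, ints):
        d = np.array(ints, dtype=float) / 4.0
        w_exp, p_exp = wilcoxon_enumeration_oracle(d)
        w, p = wilcoxon_signed_rank(d)
        assert w == pytest.approx(w_exp)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_normal_approx_close_to_exact_at_boundary(self, rng):
        d = rng.standard_normal(25)
        _, p_exact = wilcoxon_signed_rank(d, exact_limit=25)
        _, p_approx = wilcoxon_signed_rank(d, exact_limit=10)
        assert p_approx == pytest.approx(p_exact, abs=0.03)

    def test_matches_scipy_without_ties(self, rng):
        d = rng.standard_normal(14)
        w, p = wilcoxon_signed_rank(d)
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
        # scipy reports the smaller of the two one-sided statistics' sum;
        # statistics differ by convention, p-values must agree
        assert p == pytest.approx(res.pvalue, abs=1e-10)


class TestFriedmanImanDavenport:
    def test_identical_methods_give_p_one(self):
        table = pd.DataFrame(np.tile([3.0, 3.0, 3.0], (5, 1)))
        s = friedman_iman_davenport(table)
        assert s.chi2_friedman == pytest.approx(0.0)
        assert s.p_value == pytest.approx(1.0)

    def test_hand_three_by_three(self):
        # rows rank to (1,2,3),(1,2,3),(2,1,3): chi2 = 14/3, F_ID = 7,
        # p = F.sf(7; 2, 4) = 4/81
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [8.0, 7.0, 9.0]],
            columns=["a", "b", "c"],
        )
        s = friedman_iman_davenport(table)
        assert s.chi2_friedman == pytest.approx(14 / 3)
        assert s.f_iman_davenport == pytest.approx(7.0)
        assert s.p_value == pytest.approx(4 / 81)

    def test_average_ranks_sum_invariant(self, rng):
        for _ in range(10):
            b, k = rng.integers(2, 8), rng.integers(2, 6)
            table = pd.DataFrame(rng.standard_normal((b, k)))
            s = friedman_iman_davenport(table)
            assert s.average_ranks.sum() == pytest.approx(k * (k + 1) / 2)

    def test_unanimous_ordering_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((12, 1))
        table = pd.DataFrame(np.hstack([base + j for j in range(4)]))
        s = friedman_iman_davenport(table)
        assert s.p_value < 1e-6
        np.testing.assert_allclose(s.average_ranks, [1, 2, 3, 4])

    def test_missing_cells_rejected(self):
        table = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            friedman_iman_davenport(table)

    def test_pairwise_wilcoxon_matches_direct_call(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.standard_normal((8, 3)), columns=list("abc"))
        s = friedman_iman_davenport(table)
        w, p = wilcoxon_signed_rank((table["a"] - table["b"]).to_numpy())
        assert s.wilcoxon_stat.loc["a", "b"] == pytest.approx(w)
        assert s.wilcoxon_p.loc["a", "b"] == pytest.approx(p)


class TestReplicateBenchmark:
    CFG = SyntheticConfig(nodesize_grid=(1, 5, 25), ntree=25, seed=0)

    def test_single_rep_row_per_method(self):
        spec = GeneratorSpec(name="friedman1", n=60, seed=3)
        res = replicate_benchmark(
            spec, methods=("RF", "SRF"), reps=1, n_test=80, config=self.CFG
        )
        assert len(res) == 2
        assert set(res["method"]) == {"RF", "SRF"}

    def test_methods_share_draws(self):
        spec = GeneratorSpec(name="friedman1", n=60, seed=3)
        res = replicate_benchmark(
            spec, methods=("RF", "SRF"), reps=2, n_test=80, config=self.CFG
        )
        by_rep = res.groupby("rep")[["train_seed", "test_seed"]].nunique()
        assert (by_rep == 1).all().all()

    def test_reproducible(self):
        spec = GeneratorSpec(name="twonorm", n=60, seed=5)
        a = replicate_benchmark(spec, methods=("SRF",), reps=2, n_test=80, config=self.CFG)
        b = replicate_benchmark(spec, methods=("SRF",), reps=2, n_test=80, config=self.CFG)
        pd.testing.assert_frame_equal(a, b)

    def test_summarize_rejects_duplicates(self):
        rows = pd.DataFrame(
            {
                "dataset": ["d", "d"],
                "rep": [0, 0],
                "method": ["RF", "RF"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            summarize_benchmark(rows)
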