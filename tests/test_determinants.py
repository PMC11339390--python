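import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from todsense import (
    ValidationError,
    bland_altman,
    dominance_analysis,
    lda_contributions,
    pairwise_correlation,
    pca_loadings,
    predict_todmr,
    rank_mean_abs_r,
    simulate_expression_matrix,
    spearman_gene_correlation,
)


def shapley_ordering_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent oracle: average marginal R^2 gain over all k! orderings."""

    def r2(cols):
        if not cols:
            return 0.0
        A = np.column_stack([np.ones(len(y)), X[:, list(cols)]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)

    k = X.shape[1]
    shap = np.zeros(k)
    for order in permutations(range(k)):
        prev, r_prev = [], 0.0
        for i in order:
            cur = sorted(prev + [i])
            r = r2(cur)
            shap[i] += r - r_prev
            prev, r_prev = cur, r
    return shap / math.factorial(k)


@pytest.fixture
def orthogonal_pair():
    x1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
    x2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
    X = pd.DataFrame({"a": x1, "b": x2})
    return X, pd.Series(x1 + x2)


class TestPairwiseCorrelation:
    def test_perfect_linear(self):
        x = pd.DataFrame({"f": np.arange(10.0)})
        out = pairwise_correlation(x, pd.Series(2 * np.arange(10.0)))
        assert out.loc["f", "r"] == pytest.approx(1.0)
        assert out.loc["f", "r2"] == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = pd.DataFrame({"f": np.arange(10.0)})
        out = pairwise_correlation(x, pd.Series(-np.arange(10.0)))
        assert out.loc["f", "r"] == pytest.approx(-1.0)

    def test_null_features_weak_on_average(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(200):
            x = pd.DataFrame({"f": rng.normal(size=10)})
            y = pd.Series(rng.normal(size=10))
            rs.append(abs(pairwise_correlation(x, y).loc["f", "r"]))
        assert np.mean(rs) < 0.35

    def test_zero_variance_feature_skipped(self):
        x = pd.DataFrame({"f": np.ones(6), "g": np.arange(6.0)})
        out = pairwise_correlation(x, pd.Series(np.arange(6.0)))
        assert out.loc["f", "skipped"]
        assert np.isnan(out.loc["f", "r"])

    def test_rank_mean_abs_r(self):
        per_drug = {
            "d1": pd.DataFrame({"r": [0.9, 0.1]}, index=["a", "b"]),
            "d2": pd.DataFrame({"r": [-0.7, 0.3]}, index=["a", "b"]),
        }
        out = rank_mean_abs_r(per_drug)
        assert out.index[0] == "a"
        assert out.loc["a", "mean_abs_r"] == pytest.approx(0.8)


class TestSpearmanGenes:
    def test_monotone_transform_perfect_rho(self):
        expr, outcome = simulate_expression_matrix(8, ["g1", "g2"], seed=1)
        outcomes = pd.DataFrame({m: [np.exp(expr.loc["g1", m])] for m in expr.columns},
                                index=["drug"])
        rho, pval, _ = spearman_gene_correlation(expr, outcomes)
        assert rho.loc["drug", "g1"] == pytest.approx(1.0)

    def test_reversed_outcome_flips_sign(self):
        expr, _ = simulate_expression_matrix(8, ["g1", "g2"], seed=1)
        outcomes = pd.DataFrame({m: [-expr.loc["g1", m]] for m in expr.columns},
                                index=["drug"])
        rho, _, _ = spearman_gene_correlation(expr, outcomes)
        assert rho.loc["drug", "g1"] == pytest.approx(-1.0)

    def test_constant_gene_missing(self):
        expr, _ = simulate_expression_matrix(8, ["g1", "g2"], seed=1)
        expr.loc["g2"] = 1.0
        outcomes = pd.DataFrame({m: [expr.loc["g1", m]] for m in expr.columns},
                                index=["drug"])
        rho, _, _ = spearman_gene_correlation(expr, outcomes)
        assert np.isnan(rho.loc["drug", "g2"])

    def test_planted_gene_attains_max_rho(self):
        wins = 0
        n_seeds = 50
        genes = [f"g{i}" for i in range(6)]
        for seed in range(n_seeds):
            expr, outcome = simulate_expression_matrix(
                10, genes, planted=[("g3", 1.0)], outcome_noise_sd=0.5, seed=seed
            )
            outcomes = outcome.to_frame().T
            outcomes.index = ["drug"]
            rho, _, _ = spearman_gene_correlation(expr, outcomes)
            if rho.loc["drug"].abs().idxmax() == "g3":
                wins += 1
        assert wins >= 0.9 * n_seeds


class TestPredict:
    def test_exact_linear_prediction(self):
        train_x = pd.DataFrame({"f": np.arange(8.0)})
        train_y = pd.Series(3 * np.arange(8.0) + 1)
        preds = predict_todmr(train_x, train_y, pd.DataFrame({"f": [2.0]}))
        assert preds["f"].iloc[0] == pytest.approx(7.0)

    def test_screen_rejects_noise_feature(self):
        # under the null, |r| >= 0.5 at n = 10 has probability ~0.14, so the
        # screen drops a pure-noise feature in roughly 86% of draws
        rng = np.random.default_rng(0)
        dropped = 0
        n_seeds = 200
        for _ in range(n_seeds):
            x = pd.DataFrame({"signal": np.arange(10.0), "noise": rng.normal(size=10)})
            y = pd.Series(np.arange(10.0) + rng.normal(0, 0.1, 10))
            preds = predict_todmr(x, y, x.iloc[:1])
            if "noise" not in preds.attrs.get("screened_features", []):
                dropped += 1
        assert dropped >= 0.75 * n_seeds

    def test_no_predictive_feature_flagged(self):
        x = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]})
        y = pd.Series([1.0, -1, 1, -1, 1, -1])
        preds = predict_todmr(x, y, x)
        assert preds.attrs.get("no_predictive_feature", False)
        assert preds.empty or preds.shape[1] == 0

    def test_missing_screened_feature_propagates(self):
        train_x = pd.DataFrame({"f": np.arange(8.0)})
        train_y = pd.Series(np.arange(8.0))
        preds = predict_todmr(train_x, train_y, pd.DataFrame({"f": [np.nan]}))
        assert np.isnan(preds["f"].iloc[0])


class TestBlandAltman:
    def test_perfect_agreement(self):
        out = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["bias"] == 0.0
        assert out["loa_low"] == out["loa_high"] == 0.0

    def test_constant_offset(self):
        out = bland_altman(np.array([1.05, 2.05]), np.array([1.0, 2.0]))
        assert out["bias"] == pytest.approx(0.05)
        assert out["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_limits(self):
        out = bland_altman(np.array([0.9, 2.1]), np.array([1.0, 2.0]))
        sd = np.std([-0.1, 0.1], ddof=1)
        assert out["bias"] == pytest.approx(0.0, abs=1e-12)
        assert out["loa_high"] == pytest.approx(1.96 * sd)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [1.0])


class TestDominance:
    def test_single_feature_share_equals_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 2 * x + rng.normal(0, 0.5, 12)
        X = pd.DataFrame({"f": x})
        res = dominance_analysis(X, pd.Series(y))
        assert res.shares["f"] == pytest.approx(res.total, abs=1e-12)
        assert res.percent["f"] == pytest.approx(100.0)

    def test_orthogonal_equal_features_split_evenly(self, orthogonal_pair):
        X, y = orthogonal_pair
        res = dominance_analysis(X, y)
        assert res.shares["a"] == pytest.approx(res.shares["b"], abs=1e-9)
        assert res.shares.sum() == pytest.approx(res.total, abs=1e-9)

    def test_matches_ordering_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        y = pd.Series(X["a"] + 0.5 * X["b"] + rng.normal(0, 0.3, 15))
        res = dominance_analysis(X, y)
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        oracle = shapley_ordering_oracle(Xs, y.to_numpy())
        np.testing.assert_allclose(res.shares.to_numpy(), oracle, atol=1e-9)

    def test_duplicated_feature_splits_its_share(self, orthogonal_pair):
        # with in-sample orthogonal predictors the duplicated pair's combined
        # share equals the original single-feature share exactly
        X, _ = orthogonal_pair
        rng = np.random.default_rng(1)
        y = pd.Series(X["a"] + 0.3 * X["b"] + rng.normal(0, 0.2, 8))
        single = dominance_analysis(X, y)
        dup = dominance_analysis(
            pd.DataFrame({"a": X["a"], "a2": X["a"].copy(), "b": X["b"]}), y
        )
        assert dup.shares["a"] == pytest.approx(dup.shares["a2"], abs=1e-9)
        assert dup.shares["a"] + dup.shares["a2"] == pytest.approx(
            single.shares["a"], abs=1e-9
        )
        assert "rank_deficient_design" in dup.flags

    def test_dummy_feature_gets_no_share(self, orthogonal_pair):
        X, y = orthogonal_pair
        # a third column orthogonal to both predictors and to the outcome
        dummy = np.array([1.0, -1, -1, 1, -1, 1, 1, -1])
        X3 = X.assign(d=dummy)
        res = dominance_analysis(X3, y)
        assert abs(res.shares["d"]) < 1e-9

    def test_planted_determinant_ranks_first(self):
        wins = 0
        n_seeds = 100
        rng = np.random.default_rng(0)
        for _ in range(n_seeds):
            X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["det", "n1", "n2"])
            # planted effect tuned so the feature explains about 60% of variance
            y = pd.Series(X["det"] + rng.normal(0, np.sqrt(1 / 0.6 - 1), 10))
            res = dominance_analysis(X, y)
            if res.shares.idxmax() == "det":
                wins += 1
        assert wins >= 0.9 * n_seeds


class TestLda:
    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        y = pd.Series(X["a"] + 0.1 * rng.normal(size=12))
        res = lda_contributions(X, y)
        assert res.shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(1)
        contrib = []
        for _ in range(20):
            sep = np.concatenate([rng.normal(-2, 0.3, 5), rng.normal(2, 0.3, 5)])
            X = pd.DataFrame(
                {"sep": sep, "n1": rng.normal(size=10), "n2": rng.normal(size=10)}
            )
            y = pd.Series(sep + rng.normal(0, 0.1, 10))
            contrib.append(lda_contributions(X, y).shares["sep"])
        assert np.mean(contrib) > 60.0

    def test_duplicated_features_share_equally(self):
        rng = np.random.default_rng(2)
        f = np.concatenate([rng.normal(-1, 0.4, 6), rng.normal(1, 0.4, 6)])
        X = pd.DataFrame({"a": f, "b": f.copy(), "n": rng.normal(size=12)})
        y = pd.Series(f)
        res = lda_contributions(X, y)
        assert res.shares["a"] == pytest.approx(res.shares["b"], abs=1e-6)

    def test_rescaling_a_feature_leaves_contributions(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(14, 3)), columns=list("abc"))
        y = pd.Series(X["a"] - X["b"] + 0.2 * rng.normal(size=14))
        base = lda_contributions(X, y).shares
        scaled = lda_contributions(X.assign(b=X["b"] * 1e3), y).shares
        np.testing.assert_allclose(base, scaled, atol=1e-8)

    def test_loocv_accuracy_high_for_separable_classes(self):
        rng = np.random.default_rng(4)
        f = np.concatenate([rng.normal(-3, 0.3, 6), rng.normal(3, 0.3, 6)])
        X = pd.DataFrame({"f": f, "n": rng.normal(size=12)})
        res = lda_contributions(X, pd.Series(f))
        assert res.loocv_accuracy >= 0.9

    def test_shrinkage_flagged_when_underdetermined(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(6, 8)))
        X.columns = [f"f{i}" for i in range(8)]
        y = pd.Series(X["f0"] + 0.1 * rng.normal(size=6))
        res = lda_contributions(X, y)
        assert "shrinkage_covariance" in res.flags


class TestPca:
    def test_standardization_neutralizes_raw_variance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"big": 10 * rng.normal(size=20), "small": rng.normal(size=20)})
        out = pca_loadings(X)
        # after standardization neither feature dominates the first component
        l1 = out["loadings"]["PC1"].abs()
        assert l1.max() / l1.min() < 2.0

    def test_duplicated_feature_identical_loadings(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=15)
        X = pd.DataFrame({"a": f, "b": f.copy(), "c": rng.normal(size=15)})
        out = pca_loadings(X)
        assert out["loadings"].loc["a", "PC1"] == pytest.approx(
            out["loadings"].loc["b", "PC1"], abs=1e-9
        )

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        X.columns = list("abcd")
        out = pca_loadings(X)
        assert out["explained_variance_ratio"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        out = pca_loadings(X)
        for col in out["loadings"]:
            v = out["loadings"][col]
            assert v.iloc[v.abs().values.argmax()] > 0
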