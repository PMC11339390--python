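"""Linking cellular features to time-of-day drug sensitivity.

Given a phenotype matrix (cell models x features: clock, growth and
drug-sensitivity metrics, or clock-gene expression) and a per-model outcome
(drug-specific ToD_MR), this module provides the determinant analyses:
pairwise linear regression, screened prediction with Bland-Altman
agreement, Shapley-value (dominance) decomposition of the multiple-
regression R^2, median-binarized linear discriminant contributions with
leave-one-out cross-validation, PCA loadings, and Spearman gene-outcome
correlations.  Features are standardized (zero mean, unit variance) before
every multivariate analysis so contributions are comparable across units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io import ValidationError

__all__ = [
    "AttributionResult",
    "pairwise_correlation",
    "rank_mean_abs_r",
    "spearman_gene_correlation",
    "predict_todmr",
    "bland_altman",
    "dominance_analysis",
    "lda_contributions",
    "pca_loadings",
]


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    return (X - X.mean()) / X.std(ddof=0)


@dataclass
class AttributionResult:
    """Per-feature shares of an attribution analysis.

    For ``method="shapley"`` the shares sum to the full-model R^2 and
    ``percent`` re-expresses them as percent of that R^2; for
    ``method="lda"`` the shares are already percentages summing to 100.
    """

    shares: pd.Series
    total: float
    method: str
    percent: pd.Series | None = None
    loocv_accuracy: float | None = None
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# univariate screens


def pairwise_correlation(features: pd.DataFrame, outcome: pd.Series) -> pd.DataFrame:
    """Per-feature Pearson r, simple-regression R^2 and two-sided p.

    No multiplicity adjustment is applied.  Features with zero variance on
    the shared support are skipped with a flag column.
    """
    rows = []
    for col in features.columns:
        pair = pd.concat([features[col], outcome], axis=1).dropna()
        if len(pair) < 3:
            raise ValidationError(f"feature {col!r}: fewer than 3 paired values")
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.var(x) == 0:
            rows.append({"feature": col, "r": np.nan, "r2": np.nan, "p": np.nan,
                         "n": len(pair), "skipped": True})
            continue
        r, p = pearsonr(x, y)
        rows.append({"feature": col, "r": float(r), "r2": float(r) ** 2,
                     "p": float(p), "n": len(pair), "skipped": False})
    return pd.DataFrame(rows).set_index("feature")


def rank_mean_abs_r(per_drug: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Rank features by mean |r| across drugs, with the s.e.m."""
    absr = pd.DataFrame({drug: tbl["r"].abs() for drug, tbl in per_drug.items()})
    out = pd.DataFrame(
        {
            "mean_abs_r": absr.mean(axis=1),
            "sem": absr.std(axis=1, ddof=1) / np.sqrt(absr.notna().sum(axis=1)),
            "n_drugs": absr.notna().sum(axis=1),
        }
    )
    return out.sort_values("mean_abs_r", ascending=False)


def spearman_gene_correlation(
    expression: pd.DataFrame, outcomes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Spearman rho of each clock gene against each drug's ToD_MR outcome.

    *expression* is genes x models (log2 TPM); *outcomes* is drugs x models.
    Returns (rho, p) tables of shape drugs x genes plus display orderings
    from hierarchical clustering with correlation distance and single
    linkage.  Constant genes get missing rho.
    """
    models = expression.columns.intersection(outcomes.columns)
    if len(models) < 4:
        raise ValidationError("need at least 4 shared cell models")
    rho = pd.DataFrame(index=outcomes.index, columns=expression.index, dtype=float)
    pval = rho.copy()
    for drug in outcomes.index:
        y = outcomes.loc[drug, models].astype(float)
        for gene in expression.index:
            x = expression.loc[gene, models].astype(float)
            if np.var(x) == 0:
                continue
            r, p = spearmanr(x, y)
            rho.loc[drug, gene], pval.loc[drug, gene] = r, p
    order: dict = {}
    filled = rho.fillna(0.0).to_numpy(dtype=float)
    # correlation distance needs >= 2 observations per profile
    if rho.shape[0] > 2 and rho.shape[1] >= 2:
        d = np.nan_to_num(pdist(filled, metric="correlation"), nan=1.0)
        link = linkage(d, method="single")
        order["drugs"] = [rho.index[i] for i in leaves_list(link)]
    if rho.shape[1] > 2 and rho.shape[0] >= 2:
        d = np.nan_to_num(pdist(filled.T, metric="correlation"), nan=1.0)
        link = linkage(d, method="single")
        order["genes"] = [rho.columns[i] for i in leaves_list(link)]
    return rho, pval, order


# ---------------------------------------------------------------------------
# prediction and agreement


def predict_todmr(
    train_features: pd.DataFrame,
    train_outcome: pd.Series,
    new_features: pd.DataFrame,
    r_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-feature linear predictions from features passing the |r| screen.

    Features with training |Pearson r| >= *r_threshold* each get a simple
    linear model; the returned table has one prediction column per screened
    feature plus their mean.  A new row missing a screened feature yields a
    missing prediction there.  With no passing feature the table is empty
    and carries a ``no_predictive_feature`` attribute.
    """
    corr = pairwise_correlation(train_features, train_outcome)
    passed = corr.index[(corr["r"].abs() >= r_threshold) & ~corr["skipped"]]
    preds = pd.DataFrame(index=new_features.index)
    if len(passed) == 0:
        preds.attrs["no_predictive_feature"] = True
        return preds
    for col in passed:
        pair = pd.concat([train_features[col], train_outcome], axis=1).dropna()
        slope, intercept = np.polyfit(pair.iloc[:, 0], pair.iloc[:, 1], 1)
        preds[col] = intercept + slope * new_features[col]
    preds["mean_prediction"] = preds[list(passed)].mean(axis=1)
    preds.attrs["screened_features"] = list(passed)
    return preds


def bland_altman(predicted, actual) -> dict:
    """Bias and 95% limits of agreement between predicted and actual values."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.size != actual.size or predicted.size < 2:
        raise ValidationError("bland_altman needs at least 2 paired values")
    diffs = predicted - actual
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
        "differences": diffs,
        "means": (predicted + actual) / 2.0,
    }


# ---------------------------------------------------------------------------
# attribution


def _subset_r2(Xs: np.ndarray, y: np.ndarray, cache: dict, subset: tuple) -> float:
    if subset in cache:
        return cache[subset]
    if not subset:
        cache[subset] = 0.0
        return 0.0
    A = np.column_stack([np.ones(len(y)), Xs[:, list(subset)]])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    cache[subset] = r2
    return r2


def dominance_analysis(
    features: pd.DataFrame,
    outcome: pd.Series,
    max_exact: int = 20,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AttributionResult:
    """Shapley-value decomposition of the multiple-regression R^2.

    Each feature's share is its Shapley value over all 2^k predictor
    subsets: the average, over orderings, of the incremental R^2 when the
    feature enters the model.  Shares sum to the full-model R^2
    (completeness); they are also reported as percent of that R^2.  Exact
    enumeration is used up to *max_exact* features, Monte-Carlo permutation
    sampling beyond.  Rank-deficient designs are flagged (the minimum-norm
    least-squares solution, the ridge limit, is used throughout).
    """
    data = pd.concat([features, outcome.rename("__y__")], axis=1).dropna()
    if len(data) < 3:
        raise ValidationError("dominance_analysis needs at least 3 complete rows")
    X = _standardize(data[features.columns])
    y = data["__y__"].to_numpy(dtype=float)
    Xs = X.to_numpy(dtype=float)
    k = Xs.shape[1]
    flags = []
    if np.linalg.matrix_rank(Xs) < k:
        flags.append("rank_deficient_design")
    cache: dict = {}
    shap = np.zeros(k)
    if k <= max_exact:
        fact = [math.factorial(i) for i in range(k + 1)]
        for i in range(k):
            others = [j for j in range(k) if j != i]
            for s in range(k):
                w = fact[s] * fact[k - s - 1] / fact[k]
                for sub in combinations(others, s):
                    gain = _subset_r2(Xs, y, cache, tuple(sorted(sub + (i,)))) - _subset_r2(
                        Xs, y, cache, sub
                    )
                    shap[i] += w * gain
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            order = rng.permutation(k)
            prev: tuple = ()
            r_prev = 0.0
            for i in order:
                cur = tuple(sorted(prev + (i,)))
                r_cur = _subset_r2(Xs, y, cache, cur)
                shap[i] += r_cur - r_prev
                prev, r_prev = cur, r_cur
        shap /= n_permutations
    full_r2 = _subset_r2(Xs, y, cache, tuple(range(k)))
    shares = pd.Series(shap, index=features.columns)
    percent = 100.0 * shares / full_r2 if full_r2 > 0 else shares * np.nan
    return AttributionResult(
        shares=shares, total=full_r2, method="shapley", percent=percent, flags=flags
    )


def lda_contributions(features: pd.DataFrame, outcome: pd.Series) -> AttributionResult:
    """Feature contributions of a median-split linear discriminant.

    The outcome is binarized at its median (values strictly below go to the
    low class; ties at the median to the high class, flagged).  A single-
    component LDA on standardized features yields per-feature contributions
    |coefficient| / sum |coefficients| * 100; robustness is reported as
    leave-one-out cross-validated classification accuracy.  When the class
    sizes do not exceed the feature count, a shrinkage covariance estimator
    is used and flagged.
    """
    data = pd.concat([features, outcome.rename("__y__")], axis=1).dropna()
    y = data["__y__"]
    median = float(y.median())
    labels = (y >= median).astype(int)
    flags = []
    if (y == median).any():
        flags.append("median_ties_assigned_high")
    if labels.nunique() < 2:
        raise ValidationError("median split produced a single class")
    X = data[features.columns].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        flags.append("shrinkage_covariance")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=1)
    pipe = make_pipeline(StandardScaler(), lda)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Variables are collinear")
        pipe.fit(X, labels)
        coefs = pipe[-1].coef_[0]
        acc = float(
            cross_val_score(pipe, X, labels, cv=LeaveOneOut(), scoring="accuracy").mean()
        )
    contrib = 100.0 * np.abs(coefs) / np.sum(np.abs(coefs))
    return AttributionResult(
        shares=pd.Series(contrib, index=features.columns),
        total=100.0,
        method="lda",
        loocv_accuracy=acc,
        flags=flags,
    )


def pca_loadings(features: pd.DataFrame, n_components: int | None = None) -> dict:
    """PCA of standardized features with sign-stabilized loadings.

    Returns the explained-variance fractions and the per-feature loadings;
    each component's sign is chosen so its largest-magnitude loading is
    positive.  Components are truncated to min(n_rows, n_features).
    """
    X = features.dropna()
    if len(X) < 3:
        raise ValidationError("pca_loadings needs at least 3 complete rows")
    Xs = _standardize(X).to_numpy(dtype=float)
    limit = min(Xs.shape)
    k = limit if n_components is None else min(n_components, limit)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xs)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    loadings = pd.DataFrame(
        comps.T, index=features.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return {
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "loadings": loadings,
        "scores": pd.DataFrame(
            scores, index=X.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
    }
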