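"""Attribute time-of-day sensitivity to cellular features.

Simulates an expression matrix with one planted determinant of the ToD_MR
outcome and runs the attribution chain: pairwise correlations, Shapley
(dominance) decomposition of the regression R^2, median-split LDA
contributions with leave-one-out cross-validation, and PCA loadings.
"""

import pandas as pd

import todsense as ts

genes = ["BMAL1", "PER2", "CRY1", "CRY2", "NR1D1"]
expr, tod_mr = ts.simulate_expression_matrix(
    n_models=10, genes=genes, planted=[("BMAL1", 0.8)], outcome_noise_sd=0.4, seed=4
)
features = expr.T  # models x genes

corr = ts.pairwise_correlation(features, tod_mr)
print("Pairwise Pearson correlation with ToD_MR:")
print(corr[["r", "r2", "p"]].round(3).to_string())

dom = ts.dominance_analysis(features, tod_mr)
print(f"\nShapley decomposition of the full-model R^2 = {dom.total:.3f}:")
print(dom.percent.round(1).rename("% of R^2").to_string())

lda = ts.lda_contributions(features, tod_mr)
print(f"\nLDA contributions (median-split classes, LOOCV accuracy "
      f"{lda.loocv_accuracy:.2f}):")
print(lda.shares.round(1).rename("%").to_string())

pca = ts.pca_loadings(features, n_components=2)
print("\nPCA: explained variance fractions "
      f"{[round(float(v), 2) for v in pca['explained_variance_ratio'][:2]]}")
print(pca["loadings"].round(2).to_string())

print("\nThe planted gene (BMAL1) should carry the largest correlation and "
      "attribution shares; the remaining genes act as noise features.")
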