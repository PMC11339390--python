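"""Growth-rate-inhibition (GR) drug-sensitivity metrics.

The GR framework normalizes the drug effect to a single cell division:
GR(c) = 2^(k(c)/k(0)) - 1, where k(c) and k(0) are the exponential growth
rates under dose c and in the untreated control.  GR = 1 means no effect,
0 complete cytostasis, and values in (-1, 0) net cell death.  Fitting the
dose-dependent GR values to the sigmoid

    GR(c) = GRinf + (1 - GRinf) / (1 + (c / GEC50)^h)

yields GRinf (effect at infinite dose), GEC50 (half-maximal-effect dose),
the Hill slope h, and derived metrics GR50 (dose where GR = 0.5, defined
only when GRinf < 0.5) and GR_AOC (mean of 1 - GR over log10 dose).
Classical EC50/Emin values come from a separate sigmoid fitted to final
counts normalized to control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import curve_fit

from .io import ValidationError

__all__ = [
    "DoseResponseFit",
    "ClusterResult",
    "growth_rate_inhibition",
    "gr_sigmoid",
    "fit_gr_curve",
    "gr50_from_fit",
    "gr_aoc",
    "fit_ec50",
    "normalize_gec50_for_clustering",
    "cluster_matrix",
]

HILL_BOUNDS = (0.1, 5.0)  # Eq.-5 slope bounds (GR-metrics convention)
EC_HILL_BOUNDS = (0.5, 10.0)


def growth_rate_inhibition(k_treated, k_control: float):
    """GR value 2^(k_treated / k_control) - 1.

    Strictly increasing in ``k_treated``; equals 1 when treated and control
    rates agree, 0 at complete cytostasis (k_treated = 0), and is negative
    exactly when the treated population declines.
    """
    if not k_control > 0:
        raise ValidationError("control must grow: k_control > 0 required")
    return 2.0 ** (np.asarray(k_treated, dtype=float) / k_control) - 1.0


def gr_sigmoid(c, grinf, gec50, hill):
    """Dose-response sigmoid for GR values."""
    c = np.asarray(c, dtype=float)
    return grinf + (1.0 - grinf) / (1.0 + (c / gec50) ** hill)


@dataclass
class DoseResponseFit:
    """Per-dose GR values plus fitted sensitivity parameters."""

    doses: np.ndarray
    gr_values: np.ndarray
    grinf: float = np.nan
    gec50: float = np.nan
    hill: float = np.nan
    fit_r2: float = np.nan
    gr50: float = np.nan
    gr_aoc: float = np.nan
    ec50: float = np.nan
    emin: float = np.nan
    hill_ec: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def fit_gr_curve(doses, gr_values) -> DoseResponseFit:
    """Bounded multi-start least-squares fit of the GR sigmoid.

    Requires at least 4 distinct positive doses.  GRinf is bounded to
    [-1, 1], GEC50 to [min dose / 10, max dose * 10] and the Hill slope to
    [0.1, 5]; three starts spread GEC50 across the dose range.  A flat
    response (variance < 1e-4) is flagged degenerate with GEC50 missing.
    """
    doses = np.asarray(doses, dtype=float)
    gr_values = np.asarray(gr_values, dtype=float)
    pos = doses > 0
    c, g = doses[pos], gr_values[pos]
    if np.unique(c).size < 4:
        raise ValidationError("fit_gr_curve needs at least 4 distinct positive doses")
    fit = DoseResponseFit(doses=doses, gr_values=gr_values)
    if float(np.var(g)) < 1e-4:
        fit.flags.append("degenerate")
        fit.grinf = float(np.mean(g))
        fit.gr_aoc = gr_aoc(c, g)
        return fit
    lo = [-1.0, c.min() / 10.0, HILL_BOUNDS[0]]
    hi = [1.0, c.max() * 10.0, HILL_BOUNDS[1]]
    params, sse = None, np.inf
    for gec50_start in (np.sqrt(c.min() * c.max()), c.min(), c.max()):
        p0 = [np.clip(g.min(), -1, 1), gec50_start, 1.0]
        try:
            p, _ = curve_fit(gr_sigmoid, c, g, p0=p0, bounds=(lo, hi), maxfev=5000)
        except RuntimeError:
            continue
        resid = g - gr_sigmoid(c, *p)
        s = float(resid @ resid)
        if s < sse:
            params, sse = p, s
    if params is None:
        fit.flags.append("fit_failed")
        return fit
    fit.grinf, fit.gec50, fit.hill = (float(v) for v in params)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    fit.fit_r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan
    fit.gr50 = gr50_from_fit(fit)
    fit.gr_aoc = gr_aoc(c, g)
    return fit


def gr50_from_fit(fit: DoseResponseFit) -> float:
    """Closed-form dose at which the fitted sigmoid crosses GR = 0.5.

    Missing (NaN) whenever GRinf >= 0.5, where the sigmoid never reaches
    0.5 from above.
    """
    if not np.isfinite(fit.grinf) or fit.grinf >= 0.5:
        return np.nan
    ratio = (1.0 - fit.grinf) / (0.5 - fit.grinf) - 1.0
    return float(fit.gec50 * ratio ** (1.0 / fit.hill))


def gr_aoc(doses, gr_values) -> float:
    """Area over the GR curve: mean of (1 - GR) over log10 dose.

    Trapezoidal integral normalized by the spanned log10-dose range, so
    panels with different dose ranges are comparable; 0 for an all-ones
    (no-effect) curve and 1 for complete cytostasis at every dose.
    """
    doses = np.asarray(doses, dtype=float)
    gr_values = np.asarray(gr_values, dtype=float)
    pos = doses > 0
    c, g = doses[pos], gr_values[pos]
    if np.unique(c).size < 2:
        raise ValidationError("gr_aoc needs at least 2 distinct positive doses")
    order = np.argsort(c)
    x = np.log10(c[order])
    return float(np.trapezoid(1.0 - g[order], x) / (x[-1] - x[0]))


def fit_ec50(doses, relative_final_counts) -> tuple[float, float, float]:
    """Classical EC50 sigmoid fit to final counts normalized to control.

    f(c) = Emin + (1 - Emin) / (1 + (c/EC50)^h), with Emin restricted to
    [0, 1] and h to [0.5, 10].  Returns (ec50, emin, hill); parameters
    pinned at a bound on a cytotoxic (sub-zero) response are flagged via a
    warning.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(relative_final_counts, dtype=float)
    pos = doses > 0
    c, yy = doses[pos], y[pos]
    if np.unique(c).size < 4:
        raise ValidationError("fit_ec50 needs at least 4 distinct positive doses")
    if float(np.var(yy)) < 1e-4:
        warnings.warn("flat normalized counts: EC50 fit degenerate")
        return np.nan, float(np.mean(yy)), np.nan

    def f(cc, emin, ec50, h):
        return emin + (1.0 - emin) / (1.0 + (cc / ec50) ** h)

    lo = [0.0, c.min() / 10.0, EC_HILL_BOUNDS[0]]
    hi = [1.0, c.max() * 10.0, EC_HILL_BOUNDS[1]]
    best, sse = None, np.inf
    for ec_start in (np.sqrt(c.min() * c.max()), c.min(), c.max()):
        try:
            p, _ = curve_fit(
                f, c, yy, p0=[np.clip(yy.min(), 0, 1), ec_start, 1.5],
                bounds=(lo, hi), maxfev=5000,
            )
        except RuntimeError:
            continue
        s = float(np.sum((yy - f(c, *p)) ** 2))
        if s < sse:
            best, sse = p, s
    if best is None:
        warnings.warn("EC50 fit did not converge")
        return np.nan, np.nan, np.nan
    emin, ec50, h = (float(v) for v in best)
    if emin <= 1e-9 and yy.min() < -0.05:
        warnings.warn("Emin pinned at 0 for a cytotoxic response; fit quality poor")
    return ec50, emin, h


def normalize_gec50_for_clustering(
    gec50: pd.Series, reference_dose: pd.Series
) -> pd.Series:
    """GEC50 values relative to each drug's reference (approximate GRinf) dose."""
    return gec50 / reference_dose.reindex(gec50.index)


@dataclass
class ClusterResult:
    matrix: pd.DataFrame  # imputed values actually clustered
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """UPGMA (average-linkage, Euclidean) clustering with nearest-column imputation.

    Missing cells are filled from the column minimizing the Euclidean
    distance over jointly observed rows before clustering; all-missing
    columns are dropped with a warning.  Row and column dendrogram leaf
    orders are deterministic.
    """
    m = matrix.astype(float).copy()
    all_missing = [c for c in m.columns if m[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing columns: {all_missing}")
        m = m.drop(columns=all_missing)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("cluster_matrix needs at least a 2x2 matrix")
    for col in m.columns:
        nulls = m[col].isna()
        if not nulls.any():
            continue
        best, best_d = None, np.inf
        for donor in m.columns:
            if donor == col or m[donor].isna().any():
                pass  # donors may have missing cells too; require shared support
            shared = (~m[col].isna()) & (~m[donor].isna())
            if donor == col or not shared.any() or m.loc[nulls, donor].isna().any():
                continue
            d = float(np.sqrt(np.mean((m.loc[shared, col] - m.loc[shared, donor]) ** 2)))
            if d < best_d:
                best, best_d = donor, d
        if best is None:
            raise ValidationError(f"no donor column available to impute {col!r}")
        m.loc[nulls, col] = m.loc[nulls, best]
    row_link = linkage(m.to_numpy(), method="average", metric="euclidean")
    col_link = linkage(m.to_numpy().T, method="average", metric="euclidean")
    return ClusterResult(
        matrix=m,
        row_order=[m.index[i] for i in leaves_list(row_link)],
        col_order=[m.columns[i] for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
    )
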