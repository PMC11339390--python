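"""Growth-curve smoothing, doubling times and exponential growth rates.

Trajectories are smoothed with robust locally weighted quadratic regression
(tricube distance weights, bisquare robustifying reweighting), then reduced
to a doubling time over a fixed horizon and an exponential rate k fitted to
counts normalized to the first timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import GrowthTrace, ReporterTrace, ValidationError

__all__ = ["GrowthFit", "smooth_growth", "doubling_time", "fit_exponential_rate"]


@dataclass
class GrowthFit:
    """Exponential-rate fit y(t) = y0 * exp(k t) with y0 fixed at 1.

    ``doubling_time_h`` = ln 2 / k; negative for declining populations.
    ``fallback`` marks estimates recovered by log-linear regression after a
    non-convergent nonlinear fit.
    """

    k: float
    r2: float
    doubling_time_h: float
    y0: float = 1.0
    fallback: bool = False


def smooth_growth(
    trace: ReporterTrace,
    span_fraction: float = 0.1,
    robust_iterations: int = 4,
) -> ReporterTrace:
    """Robust local quadratic regression smoothing of a growth trajectory.

    Each point is re-estimated from a weighted quadratic fit over its
    nearest neighbours (window = *span_fraction* of the points, at least 7)
    with tricube distance weights; bisquare weights computed from the
    residuals down-weight outliers over *robust_iterations* passes.  Output
    values are floored at 0.
    """
    y = np.asarray(trace.values, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    n = y.size
    if n < 10:
        raise ValidationError("smooth_growth needs at least 10 points")
    span = int(np.ceil(span_fraction * n))
    if span < 7:
        warnings.warn(f"span widened from {span} to 7 points for a stable quadratic fit")
        span = 7
    span = min(span, n)

    robust_w = np.ones(n)
    smoothed = y.copy()
    half = span // 2
    for _ in range(robust_iterations + 1):
        smoothed = _loess_quadratic_pass(t, y, span, robust_w)
        resid = y - smoothed
        # bisquare weights against the *local* residual scale: growth data are
        # strongly heteroscedastic, so a global MAD would zero out the
        # well-fitted large-count tail
        robust_w = np.ones(n)
        for i in range(n):
            lo = max(0, min(i - half, n - span))
            mad = float(np.median(np.abs(resid[lo : lo + span])))
            if mad <= 1e-9 * max(abs(y[i]), 1e-300):
                continue  # window fits at numerical noise level
            u = resid[i] / (6.0 * mad)
            robust_w[i] = (1 - u**2) ** 2 if abs(u) < 1 else 0.0
    out = trace.replace(values=np.clip(smoothed, 0.0, None))
    out.meta = {**trace.meta, "smoothed": "rloess", "span": span}
    return out


def _loess_quadratic_pass(t, y, span, robust_w):
    n = y.size
    half = span // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - span))
        hi = lo + span
        tt, yy = t[lo:hi], y[lo:hi]
        d = np.abs(tt - t[i])
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        w = w * robust_w[lo:hi]
        if w.sum() <= 0:
            w = np.ones_like(d)
        x = tt - t[i]
        X = np.column_stack([np.ones_like(x), x, x**2])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yy * sw, rcond=None)
        out[i] = beta[0]
    return out


def doubling_time(trace: ReporterTrace, t: float = 96.0) -> float:
    """Horizon-based doubling time t * ln2 / ln(y_t / y_0), in hours.

    Positive for growing, negative for declining populations.  A static
    trajectory (y_t == y_0) has no finite doubling time and returns NaN.
    The value at the horizon is linearly interpolated between samples.
    """
    t0 = trace.times[0]
    y0 = float(trace.values[0])
    if t0 + t > trace.times[-1] + 1e-9:
        raise ValidationError(
            f"horizon {t} h extends {t0 + t - trace.times[-1]:.3g} h past the recording"
        )
    yt = float(np.interp(t0 + t, trace.times, trace.values))
    if y0 <= 0 or yt <= 0:
        raise ValidationError("doubling_time requires positive counts at 0 and t")
    if yt == y0:
        warnings.warn("static trajectory: doubling time undefined")
        return np.nan
    return t * np.log(2.0) / np.log(yt / y0)


def fit_exponential_rate(trace: ReporterTrace) -> GrowthFit:
    """Least-squares exponential rate of a (smoothed) growth trajectory.

    Counts are normalized to the first timepoint, fixing y0 = 1, and
    y = exp(k t) is fitted by nonlinear least squares.  On non-convergence
    the log-linear regression slope is returned instead, flagged.
    """
    y = np.asarray(trace.values, dtype=float)
    if y[0] <= 0:
        raise ValidationError("first timepoint must be positive to normalize")
    yn = y / y[0]
    t = trace.times - trace.times[0]
    pos = yn > 0
    k0 = (
        float(np.polyfit(t[pos], np.log(yn[pos]), 1)[0]) if pos.sum() >= 2 else 0.0
    )
    fallback = False
    try:
        (k,), _ = curve_fit(lambda tt, kk: np.exp(kk * tt), t, yn, p0=[k0], maxfev=2000)
    except RuntimeError:
        k, fallback = k0, True
    fitted = np.exp(k * t)
    ss_res = float(np.sum((yn - fitted) ** 2))
    ss_tot = float(np.sum((yn - yn.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dt_h = np.log(2.0) / k if k != 0 else np.nan
    return GrowthFit(k=float(k), r2=r2, doubling_time_h=dt_h, fallback=fallback)
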