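"""Time-of-day (ToD) sensitivity profiles and the chronotherapeutic index.

A ToD experiment resets the circadian clock of parallel cultures at
staggered times and treats them all at one or two wall-clock times, so the
elapsed time between reset and treatment spans the circadian cycle.  The
response at each circadian time is the fold change in cell number over a
fixed horizon after treatment, expressed relative to circadian time 0.  A
cubic smoothing spline through the relative responses gives the ToD
response curve; its max - min is the ToD maximum range (ToD_MR).  Comparing
a cancer model's curve with a non-malignant reference yields the treatment
times of maximum and minimum benefit and, averaged over drugs or models,
the chronotherapeutic index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .io import GrowthTrace, ReporterTrace, ValidationError

__all__ = [
    "ToDProfile",
    "BenefitAnnotation",
    "schedule_circadian_times",
    "tod_response",
    "build_tod_curve",
    "benefit_times",
    "chronotherapeutic_index",
    "benefit_time_histogram",
]

GRID_STEP = 0.1  # hours; dense evaluation grid for smoothed curves


def schedule_circadian_times(resets, treatments) -> pd.DataFrame:
    """Map (reset, treatment) pairs to circadian times.

    Circadian time = (treatment - reset) - 24 h, so the standard design
    (resets 0/4/8 h, treatments 32/48 h) yields {0, 4, 8, 16, 20, 24}.
    Values can be negative for non-standard designs; a mod-24 column is
    reported alongside.
    """
    rows = []
    for reset in resets:
        for treat in treatments:
            if treat < reset:
                raise ValidationError(
                    f"treatment at {treat} h precedes reset at {reset} h"
                )
            ct = (treat - reset) - 24.0
            rows.append(
                {
                    "reset_time_h": float(reset),
                    "treatment_time_h": float(treat),
                    "circadian_time": ct,
                    "circadian_time_mod24": ct % 24.0,
                }
            )
    return pd.DataFrame(rows)


def tod_response(
    counts: ReporterTrace,
    treatment_time: float,
    horizon: float = 96.0,
    smooth_window_h: float = 4.0,
) -> float:
    """Fold change in (smoothed) cell number over the evaluation horizon.

    Counts are smoothed with a centered moving average over
    *smooth_window_h* hours, then the response is
    N(treatment + horizon) / N(treatment), keeping the treatment-to-
    evaluation window identical across circadian times.
    """
    if treatment_time + horizon > counts.times[-1] + 1e-9:
        raise ValidationError(
            f"horizon ends {treatment_time + horizon - counts.times[-1]:.3g} h "
            "past the recording"
        )
    if treatment_time < counts.times[0] - 1e-9:
        raise ValidationError("treatment precedes the recording")
    w = max(int(round(smooth_window_h / counts.dt)) | 1, 1)
    kernel = np.ones(w) / w
    pad = w // 2
    ext = np.concatenate(
        [counts.values[pad:0:-1], counts.values, counts.values[-2 : -pad - 2 : -1]]
    )
    smoothed = np.convolve(ext, kernel, mode="valid") if w > 1 else counts.values
    n_t = float(np.interp(treatment_time, counts.times, smoothed))
    n_end = float(np.interp(treatment_time + horizon, counts.times, smoothed))
    if n_t <= 0:
        raise ValidationError("count at treatment must be positive")
    return n_end / n_t


@dataclass
class ToDProfile:
    """Relative ToD responses, their smoothed curve and the ToD_MR."""

    circadian_times: np.ndarray
    raw_responses: np.ndarray  # per-time mean fold change
    relative_responses: np.ndarray  # divided by the response at time 0
    grid: np.ndarray
    smoothed_curve: np.ndarray
    tod_mr: float
    tod_mr_raw: float
    dispersion: np.ndarray | None = None  # s.d. across plates per time
    label: str = ""

    @classmethod
    def from_dense(cls, grid: np.ndarray, values: np.ndarray, label: str = "") -> "ToDProfile":
        """Wrap an externally computed dense curve (e.g. an analytic model)."""
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        return cls(
            circadian_times=grid, raw_responses=values, relative_responses=values,
            grid=grid, smoothed_curve=values,
            tod_mr=float(values.max() - values.min()),
            tod_mr_raw=float(values.max() - values.min()), label=label,
        )


def build_tod_curve(
    circadian_times,
    responses,
    smoothing: float = 0.7,
    grid_step: float = GRID_STEP,
    label: str = "",
) -> ToDProfile:
    """Smooth relative ToD responses into a dense response curve.

    Replicate responses at the same circadian time are averaged (their s.d.
    is kept as per-time dispersion) and all responses are divided by the
    mean response at circadian time 0, which must be present.  The curve is
    a cubic smoothing spline minimizing p * sum (y - f)^2 +
    (1 - p) * integral f''^2 with p = *smoothing* on an hour-scaled
    abscissa; ToD_MR is max - min of the smoothed curve on a dense grid
    (``tod_mr_raw`` gives the unsmoothed equivalent).
    """
    ct = np.asarray(circadian_times, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if ct.shape != resp.shape:
        raise ValidationError("circadian_times and responses must align")
    if not 0.0 < smoothing <= 1.0:
        raise ValidationError("smoothing parameter must lie in (0, 1]")
    times = np.unique(ct)
    if times.size < 4:
        raise ValidationError("need at least 4 distinct circadian times")
    if not np.any(np.isclose(times, 0.0)):
        raise ValidationError("missing circadian time 0: anchor for relative responses")
    means = np.array([resp[np.isclose(ct, t)].mean() for t in times])
    sds = np.array(
        [resp[np.isclose(ct, t)].std(ddof=1) if np.sum(np.isclose(ct, t)) > 1 else 0.0
         for t in times]
    )
    anchor = means[np.isclose(times, 0.0)][0]
    if anchor <= 0:
        raise ValidationError("response at circadian time 0 must be positive")
    rel = means / anchor

    lam = (1.0 - smoothing) / smoothing
    if lam == 0:
        # p -> 1: interpolation limit
        spline = make_smoothing_spline(times, rel, lam=1e-12)
    else:
        spline = make_smoothing_spline(times, rel, lam=lam)
    grid = np.arange(times.min(), times.max() + grid_step / 2, grid_step)
    curve = spline(grid)
    return ToDProfile(
        circadian_times=times, raw_responses=means, relative_responses=rel,
        grid=grid, smoothed_curve=curve,
        tod_mr=float(curve.max() - curve.min()),
        tod_mr_raw=float(rel.max() - rel.min()),
        dispersion=sds, label=label,
    )


@dataclass
class BenefitAnnotation:
    """Times of maximum/minimum differential benefit and their fold changes.

    Benefit(T) = reference_relative(T) - cancer_relative(T): positive where
    the cancer model is relatively more suppressed than the non-malignant
    reference.  Fold changes are reference / cancer, so values above 1 mean
    net benefit.  Ties are broken toward the earliest time and flagged.
    """

    t_max_benefit: float
    t_min_benefit: float
    fold_change_max: float
    fold_change_min: float
    tie_flag: bool = False
    model: str = ""
    drug: str = ""


def benefit_times(
    cancer: ToDProfile, reference: ToDProfile, model: str = "", drug: str = ""
) -> BenefitAnnotation:
    """Locate the circadian times of greatest and least differential benefit."""
    if cancer.grid.shape != reference.grid.shape or not np.allclose(
        cancer.grid, reference.grid
    ):
        raise ValidationError("benefit_times requires profiles on a common dense grid")
    benefit = reference.smoothed_curve - cancer.smoothed_curve
    i_max = int(np.argmax(benefit))  # first occurrence = earliest time
    i_min = int(np.argmin(benefit))
    tie = (
        np.sum(np.isclose(benefit, benefit[i_max], atol=1e-12)) > 1
        or np.sum(np.isclose(benefit, benefit[i_min], atol=1e-12)) > 1
    )
    return BenefitAnnotation(
        t_max_benefit=float(cancer.grid[i_max]),
        t_min_benefit=float(cancer.grid[i_min]),
        fold_change_max=float(reference.smoothed_curve[i_max] / cancer.smoothed_curve[i_max]),
        fold_change_min=float(reference.smoothed_curve[i_min] / cancer.smoothed_curve[i_min]),
        tie_flag=bool(tie),
        model=model,
        drug=drug,
    )


def chronotherapeutic_index(
    annotations: list[BenefitAnnotation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank cancer models and drugs by mean benefit-time fold change.

    Returns (per-model, per-drug) tables with the mean and s.d. of
    ``fold_change_max`` and ``fold_change_min`` across the other axis,
    sorted descending by the max-benefit index.
    """
    if not annotations:
        raise ValidationError("no benefit annotations supplied")
    df = pd.DataFrame(
        [
            {
                "model": a.model, "drug": a.drug,
                "fold_change_max": a.fold_change_max,
                "fold_change_min": a.fold_change_min,
            }
            for a in annotations
        ]
    )

    def _agg(by: str) -> pd.DataFrame:
        groups = df.groupby(by)
        out = groups.agg(
            index_max=("fold_change_max", "mean"),
            sd_max=("fold_change_max", "std"),
            index_min=("fold_change_min", "mean"),
            sd_min=("fold_change_min", "std"),
            n=("fold_change_max", "size"),
        ).sort_values("index_max", ascending=False)
        if out["index_max"].duplicated(keep=False).any():
            out.attrs["rank_ties"] = True
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    return _agg("model"), _agg("drug")


def benefit_time_histogram(times, bin_width: float = 2.0) -> pd.Series:
    """Probability-normalized circular histogram of benefit times over [0, 24).

    Times are wrapped modulo 24 (so 24 h lands in the bin of 0) and binned
    at *bin_width*-hour resolution; fractions sum to 1.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("no benefit times to bin")
    wrapped = np.mod(times, 24.0)
    edges = np.arange(0.0, 24.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(wrapped, bins=edges)
    fractions = counts / counts.sum()
    return pd.Series(fractions, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
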