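"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and a seed, so each
pipeline stage can be exercised — and its planted parameters recovered —
without access to recorded data.  The generators emulate:

* damped, noisy ~24-h reporter oscillations riding on a slowly decaying
  baseline, optionally contaminated by a 12-h ultradian component, with an
  anti-phasic two-channel variant,
* exponential or logistic cell growth with multiplicative (lognormal) noise,
* dose-response panels whose per-dose growth rates are consistent with the
  GR (growth-rate-inhibition) sigmoid, so that fitting recovers the planted
  (GRinf, GEC50, Hill),
* cosine-modulated time-of-day response ratios with a known acrophase and
  modulation depth, and
* gene-expression matrices with planted feature-outcome correlations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GrowthTrace, ReporterTrace, SampleMetadata, ValidationError

__all__ = [
    "OscillatorParams",
    "ToDSimParams",
    "STANDARD_SCHEDULE",
    "rng_for",
    "simulate_reporter_signal",
    "simulate_reporter_pair",
    "simulate_growth",
    "simulate_dose_response_panel",
    "simulate_tod_experiment",
    "simulate_expression_matrix",
]

#: 3-step clock-reset protocol crossed with two treatment times, yielding
#: circadian times {0, 4, 8, 16, 20, 24} h.
STANDARD_SCHEDULE: tuple[tuple[float, float], ...] = tuple(
    (reset, treat) for treat in (32.0, 48.0) for reset in (0.0, 4.0, 8.0)
)


def rng_for(seed: int, *keys: str) -> np.random.Generator:
    """Named random substream: one root seed, independent streams per module."""
    tags = [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tags]))


@dataclass
class OscillatorParams:
    """Damped-cosine reporter model.

    value(t) = trend_baseline * exp(-trend_decay * t)
             + amplitude * exp(-damping_rate * t) * cos(2*pi*t/period + phase)
             + ultradian_fraction * amplitude * cos(2*pi*t/12)
             + N(0, noise_sd),  clipped at 0.
    """

    period: float = 24.0
    amplitude: float = 1.0
    damping_rate: float = 0.01
    phase: float = 0.0
    trend_baseline: float = 5.0
    trend_decay: float = 0.005
    ultradian_fraction: float = 0.0
    noise_sd: float = 0.1
    duration: float = 120.0
    dt: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValidationError("period, dt and duration must be positive")
        if self.damping_rate < 0 or self.ultradian_fraction < 0 or self.noise_sd < 0:
            raise ValidationError("damping_rate, ultradian_fraction, noise_sd must be >= 0")


def _time_grid(duration: float, dt: float) -> np.ndarray:
    n = int(round(duration / dt)) + 1
    return np.arange(n) * dt


def oscillator_mean(params: OscillatorParams, t: np.ndarray) -> np.ndarray:
    """Deterministic (noise-free) component of the reporter model."""
    p = params
    return (
        p.trend_baseline * np.exp(-p.trend_decay * t)
        + p.amplitude * np.exp(-p.damping_rate * t) * np.cos(2 * np.pi * t / p.period + p.phase)
        + p.ultradian_fraction * p.amplitude * np.cos(2 * np.pi * t / 12.0)
    )


def simulate_reporter_signal(
    params: OscillatorParams,
    seed: int,
    sample_id: str = "sim",
    channel: str = "Bmal1",
    cell_model: str = "sim_model",
) -> ReporterTrace:
    """One noisy reporter trace; deterministic given (params, seed)."""
    t = _time_grid(params.duration, params.dt)
    rng = rng_for(seed, "reporter", sample_id, channel)
    values = oscillator_mean(params, t)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=t.size)
    values = np.clip(values, 0.0, None)
    meta: dict = {"params": params}
    if params.duration < 2 * params.period:
        meta["warnings"] = ["duration shorter than two periods; rhythm metrics unreliable"]
    return ReporterTrace(
        sample_id=sample_id, cell_model=cell_model, channel=channel,
        times=t, values=values, dt=params.dt, meta=meta,
    )


def simulate_reporter_pair(
    params: OscillatorParams,
    phase_offset: float = np.pi,
    seed: int = 0,
    sample_id: str = "sim",
    cell_model: str = "sim_model",
) -> tuple[ReporterTrace, ReporterTrace]:
    """Anti-phasic two-channel pair (Bmal1, Per2) with independent noise.

    The second channel follows the identical model with its phase shifted
    by *phase_offset* (default pi, i.e. anti-phase).
    """
    import dataclasses

    first = simulate_reporter_signal(
        params, seed, sample_id=sample_id, channel="Bmal1", cell_model=cell_model
    )
    shifted = dataclasses.replace(params, phase=params.phase + phase_offset)
    second = simulate_reporter_signal(
        shifted, seed, sample_id=sample_id, channel="Per2", cell_model=cell_model
    )
    return first, second


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplier with coefficient of variation *cv*."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_growth(
    k: float,
    n0: float = 1000.0,
    capacity: float | None = None,
    noise_cv: float = 0.0,
    duration: float = 96.0,
    dt: float = 2.0,
    seed: int = 0,
    sample_id: str = "well",
    channel: str = "count",
    metadata: SampleMetadata | None = None,
) -> GrowthTrace:
    """Exponential (or logistic, if *capacity* is given) count trajectory.

    Counts are multiplied by unit-mean lognormal noise with coefficient of
    variation *noise_cv*, rounded to integers and floored at 0.
    """
    t = _time_grid(duration, dt)
    if capacity is None:
        mean = n0 * np.exp(k * t)
    else:
        # logistic growth toward the carrying capacity
        mean = capacity * n0 / (n0 + (capacity - n0) * np.exp(-k * t))
    rng = rng_for(seed, "growth", sample_id)
    values = mean * _lognormal_factor(rng, noise_cv, t.size)
    values = np.clip(np.round(values), 0.0, None)
    return GrowthTrace(
        sample_id=sample_id,
        cell_model=metadata.cell_model if metadata else "sim_model",
        channel=channel, times=t, values=values, dt=dt,
        meta={"k": k, "n0": n0, "capacity": capacity}, metadata=metadata,
    )


def simulate_dose_response_panel(
    k0: float,
    grinf: float,
    gec50: float,
    hill: float,
    doses: list[float],
    noise_cv: float = 0.0,
    duration: float = 96.0,
    dt: float = 2.0,
    seed: int = 0,
    drug: str = "drug",
    cell_model: str = "sim_model",
) -> list[GrowthTrace]:
    """Growth trajectories whose per-dose rates follow the GR sigmoid.

    For each dose c the GR value is GRinf + (1 - GRinf)/(1 + (c/GEC50)^h),
    the treated rate is k(c) = k0 * log2(GR(c) + 1), and growth is simulated
    as in :func:`simulate_growth`.  A dose-0 (solvent control) trace is
    always included.
    """
    if not (-1.0 <= grinf <= 1.0) or gec50 <= 0 or hill <= 0:
        raise ValidationError("require grinf in [-1, 1], gec50 > 0, hill > 0")
    from .doseresponse import gr_sigmoid

    all_doses = [0.0] + [float(c) for c in doses if c > 0]
    traces = []
    for i, c in enumerate(all_doses):
        gr = 1.0 if c == 0 else float(gr_sigmoid(np.asarray(c), grinf, gec50, hill))
        if gr <= -1.0:
            raise ValidationError(f"dose {c}: GR(c) <= -1, treated rate undefined")
        k_c = k0 * np.log2(gr + 1.0)
        meta = SampleMetadata(
            sample_id=f"{drug}_d{i}", cell_model=cell_model,
            reporter_or_drug=drug, dose_uM=c,
        )
        traces.append(
            simulate_growth(
                k_c, noise_cv=noise_cv, duration=duration, dt=dt,
                seed=seed + i, sample_id=meta.sample_id, metadata=meta,
            )
        )
    return traces


@dataclass
class ToDSimParams:
    """Cosine-modulated time-of-day response model.

    response(T) = base_response * (1 - modulation_depth * cos(2*pi*(T - acrophase)/24)),
    evaluated at the circadian time T implied by each (reset, treatment)
    schedule entry, times unit-mean lognormal noise.
    """

    base_response: float = 2.0
    modulation_depth: float = 0.15
    acrophase: float = 12.0
    schedule: tuple[tuple[float, float], ...] = STANDARD_SCHEDULE
    noise_cv: float = 0.05
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.base_response <= 0:
            raise ValidationError("base_response must be positive")
        if not 0.0 <= self.modulation_depth < 1.0:
            raise ValidationError("modulation_depth must lie in [0, 1)")
        if self.noise_cv < 0 or self.replicates < 1:
            raise ValidationError("noise_cv >= 0 and replicates >= 1 required")


def tod_modulation(params: ToDSimParams, circadian_time) -> np.ndarray:
    """Noise-free response at circadian time T (hours)."""
    T = np.asarray(circadian_time, dtype=float)
    return params.base_response * (
        1.0 - params.modulation_depth * np.cos(2 * np.pi * (T - params.acrophase) / 24.0)
    )


def simulate_tod_experiment(params: ToDSimParams, seed: int = 0) -> pd.DataFrame:
    """Count pairs (at treatment, at treatment + horizon) per schedule entry.

    Returns a table with columns ``reset_time_h, treatment_time_h,
    circadian_time, replicate, n_at_treatment, n_at_eval, response``; the
    downstream fold change is ``n_at_eval / n_at_treatment``.
    """
    if len(params.schedule) == 0:
        raise ValidationError("schedule must contain at least one (reset, treatment) entry")
    rng = rng_for(seed, "tod")
    rows = []
    for reset, treat in params.schedule:
        T = (treat - reset) - 24.0
        base_n = 500.0 * np.exp(0.02 * treat)  # cells keep dividing until treatment
        for rep in range(params.replicates):
            resp = float(tod_modulation(params, T)) * float(
                _lognormal_factor(rng, params.noise_cv, ())
            )
            n_treat = float(np.round(base_n))
            rows.append(
                {
                    "reset_time_h": reset,
                    "treatment_time_h": treat,
                    "circadian_time": T,
                    "replicate": rep,
                    "n_at_treatment": n_treat,
                    "n_at_eval": float(np.round(n_treat * resp)),
                }
            )
    df = pd.DataFrame(rows)
    df["response"] = df["n_at_eval"] / df["n_at_treatment"]
    return df


def simulate_expression_matrix(
    n_models: int,
    genes: list[str],
    planted: list[tuple[str, float]] = (),
    outcome_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix (genes x models) with planted outcome correlations.

    Expression is Gaussian per gene (mean 5 log2 TPM, sd 1); the outcome is
    the planted linear combination of expression plus Gaussian noise.
    """
    if n_models < 3:
        raise ValidationError("need at least 3 cell models")
    unknown = [g for g, _ in planted if g not in genes]
    if unknown:
        raise ValidationError(f"planted genes not in gene list: {unknown}")
    rng = rng_for(seed, "expression")
    models = [f"model_{i:02d}" for i in range(n_models)]
    expr = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(len(genes), n_models)), index=list(genes), columns=models
    )
    outcome = np.zeros(n_models)
    for gene, effect in planted:
        outcome = outcome + effect * expr.loc[gene].to_numpy()
    if outcome_noise_sd > 0:
        outcome = outcome + rng.normal(0.0, outcome_noise_sd, size=n_models)
    return expr, pd.Series(outcome, index=models, name="tod_mr")
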