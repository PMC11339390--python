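"""End-to-end per-trace circadian phenotyping.

Chains the standard processing order — sinc detrending, amplitude
normalization, autocorrelation, wavelet ridge, 30-min resampling and
multiresolution band fractions — into one call returning the tidy metric
set used for panel-level scoring.
"""

from __future__ import annotations

import pandas as pd

from .io import AnalysisConfig, ReporterTrace, resample_trace
from .mra import band_fractions, mra_decompose
from .rhythm import (
    amplitude_normalize,
    autocorr_metrics,
    cwt_spectrum,
    detrend_sinc,
    extract_ridge,
)

__all__ = ["circadian_phenotype", "phenotype_panel"]


def circadian_phenotype(
    trace: ReporterTrace, config: AnalysisConfig | None = None
) -> dict:
    """Full clock-strength metric set for one reporter trace.

    Returns a dict with the autocorrelation peak/lag, ridge length, mean
    ridge period and amplitude, and the multiresolution band fractions
    (including circadianicity).
    """
    cfg = config or AnalysisConfig()
    detrended = detrend_sinc(trace, cutoff=cfg.detrend_cutoff)
    normalized = amplitude_normalize(detrended, window=cfg.envelope_window)
    ac = autocorr_metrics(detrended)
    spec_norm = cwt_spectrum(normalized)
    spec_raw = cwt_spectrum(detrended)
    ridge = extract_ridge(
        spec_norm,
        mode=cfg.ridge_threshold_mode,
        fixed_threshold=cfg.ridge_threshold_fixed,
        amplitude_spectrum=spec_raw,
    )
    coarse = resample_trace(detrended, cfg.mra_dt, method="block_mean")
    fractions = band_fractions(*mra_decompose(coarse))
    return {
        "sample_id": trace.sample_id,
        "cell_model": trace.cell_model,
        "channel": trace.channel,
        "ac_peak": ac.peak_value,
        "ac_lag_h": ac.lag_h,
        "ac_circadian_flag": ac.circadian_flag,
        "ridge_length_d": ridge.ridge_length_days,
        "mean_period_h": ridge.mean_period_h,
        "mean_amplitude": ridge.mean_amplitude,
        "circadianicity": fractions.circadian,
        "noise_frac": fractions.noise,
        "ultradian_frac": fractions.ultradian,
        "infradian_frac": fractions.infradian,
    }


def phenotype_panel(
    traces: list[ReporterTrace], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Apply :func:`circadian_phenotype` to a panel of traces."""
    return pd.DataFrame([circadian_phenotype(tr, config) for tr in traces])
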