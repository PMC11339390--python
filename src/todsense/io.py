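"""Data model and table input/output.

Time series are exchanged as long-format CSV tables
(``sample_id, time_h, value, channel``) with a companion metadata table
keyed by ``sample_id``.  All times are in hours internally; a ``time_min``
column is accepted on read and converted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Channel",
    "ReporterTrace",
    "GrowthTrace",
    "SampleMetadata",
    "AnalysisConfig",
    "read_timeseries_table",
    "write_timeseries_table",
    "read_expression_matrix",
    "resample_trace",
    "write_metrics",
]

Channel = Literal["Bmal1", "Per2", "count", "confluency"]

#: channels treated as growth (cell number / confluency) readouts
GROWTH_CHANNELS = ("count", "confluency")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table violates a structural invariant (e.g. duplicate times)."""


@dataclass
class ReporterTrace:
    """One time series for one sample and channel.

    Parameters
    ----------
    sample_id, cell_model : str
        Identifiers; ``cell_model`` may be empty if no metadata was joined.
    channel : str
        One of ``Bmal1``, ``Per2`` (luminescence reporters), ``count`` or
        ``confluency`` (growth readouts).
    times : ndarray
        Hours since experiment start, strictly increasing, nominally uniform.
    values : ndarray
        Non-negative signal values (arbitrary units or cell counts).
    dt : float
        Sampling interval in hours.  Must match the median successive time
        difference within 1 %.
    meta : dict
        Free-form provenance (simulation parameters, warnings, ...).
    """

    sample_id: str
    cell_model: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.size < 2:
            raise ValidationError(
                f"trace {self.sample_id!r}: times and values must be equal-length (>= 2)"
            )
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise ValidationError(f"trace {self.sample_id!r}: times not strictly increasing")
        if not self.dt > 0:
            raise ValidationError(f"trace {self.sample_id!r}: dt must be positive")
        med = float(np.median(diffs))
        if abs(med - self.dt) > 0.01 * self.dt:
            raise ValidationError(
                f"trace {self.sample_id!r}: declared dt={self.dt} does not match "
                f"median time step {med:.6g} within 1%"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Recording length in hours."""
        return float(self.times[-1] - self.times[0])

    def replace(self, **kw) -> "ReporterTrace":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kw)


@dataclass
class SampleMetadata:
    """Plate/sample annotations joined to traces by ``sample_id``."""

    sample_id: str
    cell_model: str = ""
    reporter_or_drug: str = ""
    dose_uM: float = 0.0
    reset_time_h: float | None = None
    treatment_time_h: float | None = None
    plate: str = ""
    well: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.dose_uM):
            raise ValidationError(f"sample {self.sample_id!r}: dose must be finite")
        if (
            self.reset_time_h is not None
            and self.treatment_time_h is not None
            and self.treatment_time_h < self.reset_time_h
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: treatment_time precedes reset_time"
            )


@dataclass
class GrowthTrace(ReporterTrace):
    """Cell-count or confluency trajectory for one well, with treatment metadata."""

    metadata: SampleMetadata | None = None


@dataclass
class AnalysisConfig:
    """Shared analysis constants.

    Defaults follow the study conventions: 48-h sinc detrending cutoff,
    48-h amplitude-envelope window, fixed ridge threshold 40 (white-noise
    power units), 30-min resampling before multiresolution analysis,
    spline smoothing parameter 0.7 and a 96-h evaluation horizon.
    """

    detrend_cutoff: float = 48.0
    envelope_window: float = 48.0
    ridge_threshold_mode: Literal["adaptive", "fixed"] = "fixed"
    ridge_threshold_fixed: float = 40.0
    mra_dt: float = 0.5
    spline_smoothing: float = 0.7
    tod_horizon: float = 96.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "detrend_cutoff",
            "envelope_window",
            "ridge_threshold_fixed",
            "mra_dt",
            "tod_horizon",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"AnalysisConfig.{name} must be positive")
        if not 0.0 < self.spline_smoothing <= 1.0:
            raise ValidationError("spline_smoothing must lie in (0, 1]")


# ---------------------------------------------------------------------------
# readers / writers


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_timeseries_table(
    path, metadata_path=None
) -> list[ReporterTrace]:
    """Read a long-format time-series CSV into traces.

    One trace is produced per (``sample_id``, ``channel``) pair, sorted by
    time.  If *metadata_path* is given, rows are joined by ``sample_id``;
    growth channels produce :class:`GrowthTrace` objects carrying their
    :class:`SampleMetadata`.

    Times may be given as ``time_h`` (hours) or ``time_min`` (minutes,
    converted on read).
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns and "time_min" in df.columns:
        df = df.assign(time_h=df["time_min"] / 60.0)
    _require(df, ("sample_id", "time_h", "value", "channel"), path)

    meta_by_id: dict[str, SampleMetadata] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path)
        _require(mdf, ("sample_id",), metadata_path)
        for _, row in mdf.iterrows():
            sid = str(row["sample_id"])
            meta_by_id[sid] = SampleMetadata(
                sample_id=sid,
                cell_model=str(row.get("cell_model", "") or ""),
                reporter_or_drug=str(row.get("reporter_or_drug", "") or ""),
                dose_uM=float(row.get("dose_uM", 0.0) or 0.0),
                reset_time_h=_opt_float(row.get("reset_time_h")),
                treatment_time_h=_opt_float(row.get("treatment_time_h")),
                plate=str(row.get("plate", "") or ""),
                well=str(row.get("well", "") or ""),
                replicate=str(row.get("replicate", "") or ""),
            )

    traces: list[ReporterTrace] = []
    for (sid, channel), grp in df.groupby(["sample_id", "channel"], sort=True):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise ValidationError(
                f"sample {sid!r}: duplicated (sample_id, time) rows"
            )
        values = grp["value"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(times)))
        meta = meta_by_id.get(str(sid))
        model = meta.cell_model if meta is not None else ""
        if channel in GROWTH_CHANNELS:
            traces.append(
                GrowthTrace(
                    sample_id=str(sid), cell_model=model, channel=str(channel),
                    times=times, values=values, dt=dt, metadata=meta,
                )
            )
        else:
            traces.append(
                ReporterTrace(
                    sample_id=str(sid), cell_model=model, channel=str(channel),
                    times=times, values=values, dt=dt,
                )
            )
    return traces


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    return float(x)


def write_timeseries_table(traces: Sequence[ReporterTrace], path) -> None:
    """Write traces back to the long-format CSV schema (lossless round trip)."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": tr.sample_id,
                "time_h": tr.times,
                "value": tr.values,
                "channel": tr.channel,
            }
        )
        for tr in traces
    ]
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x cell-models expression table (log2 TPM).

    The first column holds gene symbols and becomes the index.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expression table needs a gene column plus models")
    return df.set_index(df.columns[0])


def resample_trace(
    trace: ReporterTrace,
    new_dt: float,
    method: Literal["block_mean", "decimate"] = "block_mean",
) -> ReporterTrace:
    """Down-sample a trace to a coarser sampling interval.

    ``decimate`` keeps every k-th sample; ``block_mean`` (default) averages
    disjoint blocks of k samples and stamps each block with the mean of its
    member times, which suppresses measurement noise before multiresolution
    analysis.
    """
    ratio = new_dt / trace.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise ValidationError(
            f"new_dt={new_dt} is not an integer multiple of dt={trace.dt}; "
            "interpolation-based resampling is out of scope"
        )
    if k == 1:
        return trace.replace()
    if method == "decimate":
        times = trace.times[::k]
        values = trace.values[::k]
    elif method == "block_mean":
        n = (len(trace) // k) * k
        times = trace.times[:n].reshape(-1, k).mean(axis=1)
        values = trace.values[:n].reshape(-1, k).mean(axis=1)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return trace.replace(times=times, values=values, dt=float(new_dt))


def write_metrics(records, path) -> None:
    """Write tidy (entity, metric, value) records deterministically.

    Rows are sorted by entity then metric so identical inputs produce
    byte-identical files.
    """
    df = pd.DataFrame(records, columns=["entity", "metric", "value"])
    df = df.sort_values(["entity", "metric"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("entity", "metric", "value"), path)
    return df
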