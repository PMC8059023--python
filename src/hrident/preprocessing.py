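"""Raw-record preprocessing: downsample, window, detrend, mean-remove.

The 1-Hz heart-rate stream is downsampled to 0.2 Hz by averaging
consecutive batches of five samples, the evaluation window is cut out,
the output is detrended (least-squares straight line removed, which also
strips the slow Phase III drift) and the input has its mean removed so
that a balanced window leaves exactly ±half-amplitude speed levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .excitation import EvaluationWindow, SpeedProfile

__all__ = [
    "HRSeries",
    "DeviationSignal",
    "downsample_hr",
    "extract_window",
    "detrend_output",
    "remove_mean_input",
    "fill_missing",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HRSeries:
    """Uniformly sampled heart-rate series in bpm."""

    sample_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("sample_times and values must be 1-d and equal length")
        if t.size == 0:
            raise ValueError("series must be non-empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite (interpolate gaps first)")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("sample grid must be uniform")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "values", v)

    @property
    def sample_period(self) -> float:
        if self.sample_times.size < 2:
            raise ValueError("sample period undefined for a single sample")
        return float(self.sample_times[1] - self.sample_times[0])


@dataclass(frozen=True)
class DeviationSignal:
    """Zero-mean deviation signal about the operating point.

    ``kind`` is ``"input"`` (speed deviation, m/s) or ``"output"`` (HR
    deviation, bpm).  ``removed`` records the mean/trend coefficients taken
    out during preprocessing, for the JSON sidecar.
    """

    sample_times: np.ndarray
    values: np.ndarray
    kind: str
    removed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("input", "output"):
            raise ValueError("kind must be 'input' or 'output'")
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("sample_times and values must be 1-d and equal length")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "values", v)

    @property
    def sample_period(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])


def fill_missing(values: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly interpolate runs of up to ``max_gap`` missing (NaN) samples.

    Chest-strap telemetry occasionally drops samples; longer gaps are a
    data-quality failure and raise.
    """
    v = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    if isnan[0] or isnan[-1]:
        raise ValueError("cannot interpolate missing samples at the series edges")
    # find run lengths of consecutive NaNs
    idx = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    starts, ends = idx[::2], idx[1::2]
    if np.any(ends - starts > max_gap):
        raise ValueError(f"gap of more than {max_gap} consecutive missing samples")
    x = np.arange(v.size)
    v[isnan] = np.interp(x[isnan], x[~isnan], v[~isnan])
    return v


def downsample_hr(series: HRSeries, factor: int = 5) -> HRSeries:
    """Average consecutive batches of ``factor`` samples (1 Hz -> 0.2 Hz).

    A trailing remainder shorter than one batch is dropped and logged.
    Each output sample carries the time stamp of the first sample in its
    batch, so a 1-Hz grid starting at 0 s maps onto the 0, 5, 10, ... grid.
    """
    if series.values.size == 0:
        raise ValueError("cannot downsample an empty series")
    n_batches, remainder = divmod(series.values.size, factor)
    if n_batches == 0:
        raise ValueError("series shorter than one batch")
    if remainder:
        logger.info("downsample_hr: dropping %d trailing samples", remainder)
    v = series.values[: n_batches * factor].reshape(n_batches, factor).mean(axis=1)
    t = series.sample_times[: n_batches * factor : factor]
    return HRSeries(sample_times=t, values=v)


def extract_window(series, window: EvaluationWindow):
    """Inclusive slice of a series or speed profile on the window's grid."""
    t = series.sample_times
    period = t[1] - t[0]
    if abs(period - window.sample_period) > 1e-9:
        raise ValueError(
            f"series period {period} s does not match window period "
            f"{window.sample_period} s"
        )
    offset = (window.start_time - t[0]) / period
    if abs(offset - round(offset)) > 1e-6:
        raise ValueError("window start does not align with the sample grid")
    i0 = int(round(offset))
    i1 = i0 + window.n_samples
    if i0 < 0 or i1 > t.size:
        raise ValueError("window extends beyond the series span")
    if isinstance(series, SpeedProfile):
        return SpeedProfile(
            sample_times=t[i0:i1],
            speeds=series.speeds[i0:i1],
            mean_speed=series.mean_speed,
        )
    return HRSeries(sample_times=t[i0:i1], values=series.values[i0:i1])


def detrend_output(series: HRSeries) -> DeviationSignal:
    """Remove the least-squares straight line (mean plus linear trend).

    This strips the operating-point level and any slow Phase III drift in
    one step; the removed intercept/slope are recorded on the result.
    """
    if series.values.size < 3:
        raise ValueError("need at least 3 samples to detrend")
    t = series.sample_times
    slope, intercept = np.polyfit(t, series.values, 1)
    resid = series.values - (slope * t + intercept)
    return DeviationSignal(
        sample_times=t,
        values=resid,
        kind="output",
        removed={"intercept_bpm": float(intercept), "slope_bpm_per_s": float(slope)},
    )


def remove_mean_input(profile: SpeedProfile) -> DeviationSignal:
    """Subtract the window mean from the speed signal.

    On a balanced window the two PRBS levels map to exactly
    ``±half_amplitude`` about zero.
    """
    if profile.speeds.size == 0:
        raise ValueError("empty speed profile")
    m = float(profile.speeds.mean())
    return DeviationSignal(
        sample_times=profile.sample_times,
        values=profile.speeds - m,
        kind="input",
        removed={"mean_mps": m},
    )
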