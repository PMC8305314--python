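"""Signal conditioning: baseline (gravity) removal, resampling, filtering.

A phone held still before the stimulus measures the gravity vector (plus a
small sensor bias).  Because an mAAT response lasts well under a second and
the phone starts at rest, gravity is treated as a constant baseline estimated
over a pre-stimulus rest window and subtracted sample-wise — no orientation
tracking.  Devices that expose a linear accelerometer (gravity already
removed) skip the subtraction.

Phone sampling is irregular; onset detection and integration want a uniform
grid, so traces are linearly interpolated onto one (linear, not spline: no
overshoot at the movement edge).  An optional zero-phase low-pass (4th-order
Butterworth, default 20 Hz) suppresses tremor and sensor noise without
shifting the onset.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from .records import SensorTrace


class BaselineError(ValueError):
    """Too few rest samples to estimate the gravity baseline; trial unprocessable."""


@dataclass
class PrepConfig:
    """Preprocessing parameters.

    resample_rate : Hz, uniform grid rate (default 100, typical phone IMU rate).
    rest_window : seconds before stimulus onset treated as rest (default 0.3;
        the task shows a 500 ms fixation cross and starts only once the phone
        is at rest, so this window is quiescent by design).
    lowpass_cutoff : Hz, or None to disable filtering.
    """

    resample_rate: float = 100.0
    rest_window: float = 0.3
    lowpass_cutoff: Optional[float] = 20.0

    def __post_init__(self) -> None:
        if self.resample_rate <= 0:
            raise ValueError("resample_rate must be positive")
        if self.rest_window <= 0:
            raise ValueError("rest_window must be positive")
        if self.lowpass_cutoff is not None and not (
            0 < self.lowpass_cutoff < self.resample_rate / 2
        ):
            raise ValueError("lowpass_cutoff must lie in (0, resample_rate/2)")


def estimate_rest_baseline(
    trace: SensorTrace, stim_onset: float, cfg: PrepConfig
) -> np.ndarray:
    """Per-axis mean acceleration over the pre-stimulus rest window.

    For a device without a linear accelerometer the norm of the result is
    close to 9.81 m/s^2 (gravity); with one it is close to zero.
    """
    mask = (trace.t >= stim_onset - cfg.rest_window) & (trace.t <= stim_onset)
    n = int(np.count_nonzero(mask))
    if n < 5:
        raise BaselineError(
            f"only {n} samples in the {cfg.rest_window * 1e3:.0f} ms rest window "
            f"before stim_onset={stim_onset:.3f} s (need >= 5)"
        )
    return trace.acc[mask].mean(axis=0)


def remove_gravity(trace: SensorTrace, baseline: np.ndarray) -> SensorTrace:
    """Subtract the constant baseline vector; identity for linear-accelerometer data."""
    if trace.has_linear_accelerometer:
        return trace
    baseline = np.asarray(baseline, dtype=float)
    return SensorTrace(
        t=trace.t,
        acc=trace.acc - baseline[np.newaxis, :],
        gyro=trace.gyro,
        has_linear_accelerometer=True,
    )


def resample_uniform(trace: SensorTrace, rate: float) -> SensorTrace:
    """Linearly interpolate onto a uniform grid spanning [t_first, t_last].

    The grid has ``round(span * rate) + 1`` points, so both endpoints are
    preserved and an already-uniform trace at the requested rate is returned
    unchanged (up to float round-off).
    """
    t0, t1 = trace.span
    n = int(round((t1 - t0) * rate)) + 1
    if n < 3:
        raise ValueError(
            f"trace span {t1 - t0:.4f} s shorter than 2 grid steps at {rate} Hz"
        )
    grid = np.linspace(t0, t1, n)
    acc = np.column_stack(
        [np.interp(grid, trace.t, trace.acc[:, k]) for k in range(3)]
    )
    gyro = None
    if trace.gyro is not None:
        gyro = np.column_stack(
            [np.interp(grid, trace.t, trace.gyro[:, k]) for k in range(3)]
        )
    return SensorTrace(
        t=grid, acc=acc, gyro=gyro,
        has_linear_accelerometer=trace.has_linear_accelerometer,
    )


def lowpass(trace: SensorTrace, cutoff: float) -> SensorTrace:
    """Zero-phase 4th-order Butterworth low-pass, applied per axis.

    Requires a uniform grid (run :func:`resample_uniform` first).  filtfilt's
    forward-backward pass preserves onset timing.
    """
    dt = np.diff(trace.t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("lowpass requires a uniformly sampled trace")
    fs = 1.0 / dt[0]
    b, a = butter(4, cutoff / (fs / 2), btype="low")
    acc = filtfilt(b, a, trace.acc, axis=0)
    return SensorTrace(
        t=trace.t, acc=acc, gyro=trace.gyro,
        has_linear_accelerometer=trace.has_linear_accelerometer,
    )


def acc_magnitude(trace: SensorTrace) -> np.ndarray:
    """Per-sample Euclidean norm of the (gravity-free) acceleration."""
    return np.linalg.norm(trace.acc, axis=1)


def prepare_trace(
    trace: SensorTrace, stim_onset: float, cfg: Optional[PrepConfig] = None
) -> SensorTrace:
    """Full conditioning chain: baseline removal -> uniform grid -> low-pass.

    Raises :class:`BaselineError` when the rest window holds too few samples.
    """
    cfg = cfg or PrepConfig()
    if trace.has_linear_accelerometer:
        linear = trace
    else:
        baseline = estimate_rest_baseline(trace, stim_onset, cfg)
        linear = remove_gravity(trace, baseline)
    uniform = resample_uniform(linear, cfg.resample_rate)
    if cfg.lowpass_cutoff is not None:
        uniform = lowpass(uniform, cfg.lowpass_cutoff)
    return uniform
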