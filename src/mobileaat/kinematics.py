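"""Motion-onset detection, reaction time, and movement distance.

Definitions
-----------
Reaction time (mAAT RT): the time between stimulus onset and the onset of
the phone's motion.  Motion onset is the first sample whose gravity-free
acceleration magnitude strictly exceeds ``max(0.8, 0.3 * a_max)`` m/s^2,
where ``a_max`` is the maximum acceleration magnitude within the trial's
2-second response window.  The adaptive term scales the criterion with how
vigorously this participant moved on this trial; the 0.8 m/s^2 floor keeps
sensor noise from triggering on feeble trials.

Distance (mAAT distance): how far the phone travels during the outward
stroke, obtained by double time-integration of the movement-axis (z)
acceleration from motion onset, with velocity defined as zero at onset (the
phone starts at rest).  The segment ends where the movement-axis velocity
first returns to zero after its peak — the participant then reverses to
return the phone, and integrating through the return stroke would cancel the
displacement — and is capped at 1 s.  This double-integration reading of
"magnitude and duration of the acceleration" is this package's declared
interpretation; see docs/methods.md.

Direction: the sign of the net z displacement over the segment under the
``+z_toward_face`` convention — positive is a pull (approach), negative a
push (avoidance).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .preprocess import BaselineError, PrepConfig, acc_magnitude, prepare_trace
from .records import SensorTrace, TrialMetrics, TrialRecord

#: Fixed component of the onset criterion, m/s^2.
THRESHOLD_FLOOR_MS2 = 0.8
#: Adaptive component: fraction of the trial's peak acceleration magnitude.
THRESHOLD_FRACTION = 0.3

#: Velocity below this fraction of its outward peak counts as "returned to
#: zero" (guards against integration round-off and baseline-bias drift
#: keeping the velocity a hair above zero at the true stroke end).
_VEL_ZERO_FRACTION = 0.01
#: Fraction of the velocity extremum used to latch the initial movement
#: direction before locating the outward-phase peak.
_VEL_DIRECTION_FRACTION = 0.1


@dataclass
class KinConfig:
    """Response-window and segmentation parameters (seconds / meters)."""

    response_window_s: float = 2.0  # image disappears after 2 s = "no reaction"
    segment_cap_s: float = 1.0
    undetermined_displacement_m: float = 0.01

    def __post_init__(self) -> None:
        if self.response_window_s <= 0 or self.segment_cap_s <= 0:
            raise ValueError("windows must be positive")


@dataclass
class OnsetResult:
    onset_time: Optional[float]  # seconds on the trace clock; None = no onset
    threshold_used: float  # m/s^2
    a_max: float  # max magnitude in the response window, m/s^2
    window_truncated: bool = False  # trace ended before the full window


@dataclass
class MovementSegment:
    t_start: float
    t_end: float
    peak_acc: float  # max magnitude within the segment, m/s^2
    capped: bool = False  # no velocity zero-crossing before the cap

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")


def onset_threshold(a_max: float) -> float:
    """Adaptive onset criterion: ``max(0.8, 0.3 * a_max)`` m/s^2."""
    if a_max < 0:
        raise ValueError(f"a_max must be non-negative, got {a_max}")
    return max(THRESHOLD_FLOOR_MS2, THRESHOLD_FRACTION * a_max)


def detect_onset(
    t: np.ndarray,
    mag: np.ndarray,
    stim_onset: float,
    window: float = 2.0,
) -> OnsetResult:
    """First sample in the response window strictly above the adaptive threshold.

    ``a_max`` is computed over [stim_onset, stim_onset + window] of the
    current trial only; onset candidates must lie strictly after the
    stimulus.  Returns ``onset_time=None`` when no sample exceeds the
    threshold (a "no reaction" by the task's rules).
    """
    t = np.asarray(t, dtype=float)
    mag = np.asarray(mag, dtype=float)
    in_window = (t >= stim_onset) & (t <= stim_onset + window)
    if not np.any(in_window):
        return OnsetResult(None, THRESHOLD_FLOOR_MS2, 0.0, window_truncated=True)
    truncated = t[-1] < stim_onset + window
    a_max = float(mag[in_window].max())
    thr = onset_threshold(a_max)
    candidates = in_window & (t > stim_onset) & (mag > thr)
    idx = np.flatnonzero(candidates)
    if idx.size == 0:
        return OnsetResult(None, thr, a_max, window_truncated=truncated)
    return OnsetResult(float(t[idx[0]]), thr, a_max, window_truncated=truncated)


def reaction_time(onset: OnsetResult, stim_onset: float) -> Optional[float]:
    """Milliseconds from stimulus onset to motion onset; None without onset.

    Range filtering (the 200/2000 ms validity rules) is the QC stage's job,
    not this function's.
    """
    if onset.onset_time is None:
        return None
    if onset.onset_time < stim_onset:
        raise ValueError(
            f"onset {onset.onset_time:.4f} s precedes stimulus {stim_onset:.4f} s "
            "(segmentation bug)"
        )
    return (onset.onset_time - stim_onset) * 1000.0


def _require_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace is not uniformly sampled; run resample_uniform first")
    return float(dt[0])


def extract_segment(
    trace: SensorTrace, onset_time: float, cfg: Optional[KinConfig] = None
) -> MovementSegment:
    """Bound the outward stroke: onset to the first velocity zero after the peak.

    The movement-axis (z) velocity is integrated from rest at onset; the
    stroke ends where it falls back to (near) zero after its extremum, or at
    ``segment_cap_s`` when it never does (flagged ``capped``).
    """
    cfg = cfg or KinConfig()
    _require_uniform(trace.t)
    sel = np.flatnonzero(
        (trace.t >= onset_time) & (trace.t <= onset_time + cfg.segment_cap_s)
    )
    if sel.size < 2:
        raise ValueError("fewer than 2 samples between onset and the segment cap")
    t = trace.t[sel]
    az = trace.acc[sel, 2]
    vz = cumulative_trapezoid(az, t, initial=0.0)
    v_abs_max = float(np.abs(vz).max())
    capped = True
    i_end = sel.size - 1
    if v_abs_max > 0:
        # latch the direction of the *initial* motion, then take the outward
        # velocity peak; the global |v| extremum may sit in the return stroke
        first_moving = int(np.flatnonzero(np.abs(vz) >= _VEL_DIRECTION_FRACTION * v_abs_max)[0])
        sign = 1.0 if vz[first_moving] >= 0 else -1.0
        i_peak = int(np.argmax(vz * sign))
        v_peak = float(vz[i_peak] * sign)
        after = np.flatnonzero(vz[i_peak + 1 :] * sign <= _VEL_ZERO_FRACTION * v_peak)
        if after.size:
            i_end = i_peak + 1 + int(after[0])
            capped = False
    mag = acc_magnitude(SensorTrace(t=t, acc=trace.acc[sel], has_linear_accelerometer=True))
    peak_acc = float(mag[: i_end + 1].max())
    return MovementSegment(
        t_start=float(t[0]), t_end=float(t[i_end]), peak_acc=peak_acc, capped=capped
    )


def _z_displacement(trace: SensorTrace, segment: MovementSegment) -> float:
    """Signed net z displacement over the segment (double trapezoidal integral)."""
    _require_uniform(trace.t)
    sel = (trace.t >= segment.t_start - 1e-12) & (trace.t <= segment.t_end + 1e-12)
    t = trace.t[sel]
    az = trace.acc[sel, 2]
    vz = cumulative_trapezoid(az, t, initial=0.0)
    xz = cumulative_trapezoid(vz, t, initial=0.0)
    return float(xz[-1])


def compute_distance(trace: SensorTrace, segment: MovementSegment) -> float:
    """mAAT distance in meters: |double integral of z acceleration| over the segment.

    Velocity is taken as zero at onset (phone at rest).  Requires a uniform
    grid; raises otherwise, directing the caller to ``resample_uniform``.
    """
    return abs(_z_displacement(trace, segment))


def classify_direction(
    trace: SensorTrace, segment: MovementSegment, cfg: Optional[KinConfig] = None
) -> str:
    """pull / push / undetermined from the sign of the net z displacement."""
    cfg = cfg or KinConfig()
    disp = _z_displacement(trace, segment)
    if abs(disp) < cfg.undetermined_displacement_m:
        return "undetermined"
    return "pull" if disp > 0 else "push"


def process_trial(
    record: TrialRecord,
    prep_cfg: Optional[PrepConfig] = None,
    kin_cfg: Optional[KinConfig] = None,
) -> TrialMetrics:
    """Raw trial -> per-trial metrics (RT, distance, direction, provisional status).

    The status emitted here is kinematic only: ``valid`` when an onset was
    found, ``no_reaction`` when nothing crossed the threshold within the
    response window, ``no_onset`` when the trial could not be processed at
    all (e.g. no usable rest baseline).  RT-range reclassification
    (too_fast / late no_reaction) happens in the QC stage.
    """
    prep_cfg = prep_cfg or PrepConfig()
    kin_cfg = kin_cfg or KinConfig()
    base = dict(
        participant_id=record.participant_id,
        trial=record.trial if record.trial is not None else -1,
        block=record.block,
        stimulus_id=record.stimulus_id,
        category=record.category,
        instructed_direction=record.instructed_direction,
    )
    try:
        prepared = prepare_trace(record.trace, record.stim_onset, prep_cfg)
    except (BaselineError, ValueError):
        return TrialMetrics(
            **base,
            rt_ms=None,
            distance_m=None,
            peak_acc_ms2=None,
            observed_direction="undetermined",
            status="no_onset",
        )
    mag = acc_magnitude(prepared)
    onset = detect_onset(
        prepared.t, mag, record.stim_onset, window=kin_cfg.response_window_s
    )
    if onset.onset_time is None:
        status = "no_onset" if onset.window_truncated and onset.a_max == 0 else "no_reaction"
        return TrialMetrics(
            **base,
            rt_ms=None,
            distance_m=None,
            peak_acc_ms2=onset.a_max if onset.a_max > 0 else None,
            observed_direction="undetermined",
            status=status,
        )
    rt = reaction_time(onset, record.stim_onset)
    segment = extract_segment(prepared, onset.onset_time, kin_cfg)
    distance = compute_distance(prepared, segment)
    direction = classify_direction(prepared, segment, kin_cfg)
    return TrialMetrics(
        **base,
        rt_ms=rt,
        distance_m=distance,
        peak_acc_ms2=segment.peak_acc,
        observed_direction=direction,
        status="valid",
        segment_capped=segment.capped,
    )


def process_session(
    trials: list[TrialRecord],
    prep_cfg: Optional[PrepConfig] = None,
    kin_cfg: Optional[KinConfig] = None,
) -> list[TrialMetrics]:
    """Process every trial of a session in order."""
    out = []
    for i, rec in enumerate(trials):
        if rec.trial is None:
            rec.trial = i
        out.append(process_trial(rec, prep_cfg, kin_cfg))
    return out
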