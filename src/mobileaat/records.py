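"""Core data containers for phone-based approach-avoidance (mAAT) recordings.

The mobile approach-avoidance task presents food images on a phone screen and
asks the participant to pull the phone toward their face or push it away.  The
phone's inertial sensors record the response; everything downstream (reaction
time, movement distance, congruency scores) is derived from those traces.

Containers here are deliberately thin: plain dataclasses wrapping numpy
arrays, with explicit ``problems()`` methods instead of raising constructors,
so that a malformed session can be *reported on* rather than being
unrepresentable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CATEGORIES = ("palatable", "unpalatable", "dutch", "asian")
DIRECTIONS = ("pull", "push")
OBSERVED_DIRECTIONS = ("pull", "push", "undetermined")
TRIAL_STATUSES = ("valid", "too_fast", "no_reaction", "no_onset")

#: Device axis convention used throughout: +z points out of the screen toward
#: the participant's face, so a pull movement produces positive z displacement.
AXIS_CONVENTION = "+z_toward_face"

#: Median sampling-interval bounds (seconds) considered plausible for a phone
#: accelerometer stream (10 Hz .. 1 kHz).
_DT_MIN_S = 0.001
_DT_MAX_S = 0.1


@dataclass
class SensorTrace:
    """Timestamped 3-axis acceleration (and optional rotational rate) for one trial.

    Parameters
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds since trial start; strictly increasing.
    acc : ndarray, shape (n, 3)
        Acceleration in m/s^2 in the device frame.
    gyro : ndarray, shape (n, 3), optional
        Rotational rate in rad/s.  Carried through but unused by the default
        pipeline (movements are classified from linear acceleration alone).
    has_linear_accelerometer : bool
        True when the device already removed gravity from ``acc``.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: Optional[np.ndarray] = None
    has_linear_accelerometer: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def problems(self) -> list[str]:
        """Invariant violations, as human-readable strings (empty = clean)."""
        out: list[str] = []
        if self.t.ndim != 1 or self.t.size < 2:
            out.append("trace must contain at least 2 samples")
            return out
        if not np.all(np.isfinite(self.t)):
            out.append("non-finite timestamps")
        if np.any(np.diff(self.t) <= 0):
            out.append("timestamps not strictly increasing")
        if self.acc.shape != (self.t.size, 3):
            out.append(
                f"acc shape {self.acc.shape} does not match {self.t.size} samples x 3 axes"
            )
        elif not np.all(np.isfinite(self.acc)):
            out.append("non-finite acceleration samples")
        if self.gyro is not None:
            if self.gyro.shape != (self.t.size, 3):
                out.append("gyro length does not match timestamps")
            elif not np.all(np.isfinite(self.gyro)):
                out.append("non-finite gyro samples")
        if not out:
            dt = self.median_dt
            if not (_DT_MIN_S < dt < _DT_MAX_S):
                out.append(
                    f"median sampling interval {dt * 1e3:.3f} ms outside (1, 100) ms"
                )
        return out


@dataclass
class TrialRecord:
    """One stimulus presentation: metadata plus the raw sensor trace."""

    participant_id: str
    block: int
    stimulus_id: str
    category: str
    instructed_direction: str
    stim_onset: float  # seconds, on the trace clock
    trace: SensorTrace
    trial: Optional[int] = None  # index within the session (assigned on read)

    def problems(self) -> list[str]:
        out = list(self.trace.problems())
        if self.category not in CATEGORIES:
            out.append(f"unknown category {self.category!r}")
        if self.instructed_direction not in DIRECTIONS:
            out.append(f"unknown instructed_direction {self.instructed_direction!r}")
        if not out:
            t0, t1 = self.trace.span
            if not (t0 <= self.stim_onset <= t1):
                out.append(
                    f"stim_onset {self.stim_onset:.3f} s outside trace span "
                    f"[{t0:.3f}, {t1:.3f}] s"
                )
        return out


@dataclass
class RatingRecord:
    """Explicit ratings for one image: valence, arousal (EmojiGrid) and wanting (VAS).

    All three are rescaled to [0, 100] regardless of widget resolution.
    """

    participant_id: str
    stimulus_id: str
    category: str
    valence: float
    arousal: float
    wanting: float

    def problems(self) -> list[str]:
        out: list[str] = []
        for name in ("valence", "arousal", "wanting"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                out.append(f"{name} {v} outside [0, 100]")
        if self.category not in CATEGORIES:
            out.append(f"unknown category {self.category!r}")
        return out


@dataclass
class Session:
    """All data recorded from one participant."""

    participant_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    ratings: Optional[list[RatingRecord]] = None
    neophobia_score: Optional[float] = None  # food neophobia scale total, 10..70


@dataclass
class TrialMetrics:
    """Derived per-trial quantities emitted by the kinematics stage.

    ``rt_ms`` is present exactly when ``status`` is ``valid`` or ``too_fast``;
    ``distance_m`` is non-negative when present.
    """

    participant_id: str
    trial: int
    block: int
    stimulus_id: str
    category: str
    instructed_direction: str
    rt_ms: Optional[float]
    distance_m: Optional[float]
    peak_acc_ms2: Optional[float]
    observed_direction: str
    status: str
    segment_capped: bool = False

    @property
    def direction_mismatch(self) -> bool:
        """Observed movement opposite to the instruction (flagged, not excluded)."""
        return (
            self.observed_direction in DIRECTIONS
            and self.observed_direction != self.instructed_direction
        )
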