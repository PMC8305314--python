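"""Synthetic phone-motion traces and whole experiments with known ground truth.

The movement model is a minimum-jerk point-to-point stroke — the standard
description of smooth human reaching — along the device z axis:

    x(tau) = D * (10 tau^3 - 15 tau^4 + 6 tau^5),  tau = (t - t_on) / T

with analytic velocity and acceleration, so every derived quantity (onset,
peak acceleration ``(10/sqrt(3)) * D / T^2``, displacement) has a closed
form to test against.  A trial is: rest, stimulus onset, a latency, the
outward stroke, a short hold, an optional mirrored return stroke, rest.
Gravity enters as a constant vector; sensor imperfection as i.i.d. Gaussian
noise on each axis plus Gaussian jitter on the sample clock.

Experiments plant a congruency effect on RT (congruent pairings — pull
palatable/dutch, push unpalatable/asian — are faster by half the effect,
incongruent slower by half, keeping direction and category margins clean)
and an arousal-linked scaling on movement distance, mirroring the empirical
pattern that high-arousal image categories are moved further regardless of
direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .records import (
    CATEGORIES,
    DIRECTIONS,
    RatingRecord,
    Session,
    SensorTrace,
    TrialRecord,
)

STANDARD_GRAVITY = (0.0, 0.0, -9.81)

#: (category, direction) pairings congruent with the expected motivation.
CONGRUENT_PAIRS = frozenset(
    {("palatable", "pull"), ("unpalatable", "push"), ("dutch", "pull"), ("asian", "push")}
)

#: Planted explicit-rating means per category (0-100 scales), chosen to
#: mirror the qualitative ordering expected for food images: palatable and
#: own-culture (dutch) food high in valence/wanting; unpalatable and
#: own-culture food high in arousal.
RATING_MEANS = {
    "palatable": {"valence": 72.0, "arousal": 42.0, "wanting": 70.0},
    "unpalatable": {"valence": 18.0, "arousal": 66.0, "wanting": 12.0},
    "dutch": {"valence": 68.0, "arousal": 60.0, "wanting": 66.0},
    "asian": {"valence": 52.0, "arousal": 50.0, "wanting": 48.0},
}


def min_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_acceleration(t: np.ndarray, D: float, T: float, t_on: float) -> np.ndarray:
    """Analytic acceleration of a minimum-jerk stroke of displacement D, duration T."""
    tau = (np.asarray(t, dtype=float) - t_on) / T
    a = (D / T**2) * (60 * tau - 180 * tau**2 + 120 * tau**3)
    a[(tau < 0) | (tau > 1)] = 0.0
    return a


def min_jerk_peak_acceleration(D: float, T: float) -> float:
    """Closed-form peak |acceleration| of a minimum-jerk stroke: (10/sqrt 3) D/T^2."""
    return 10.0 * abs(D) / (math.sqrt(3.0) * T**2)


@dataclass
class TraceSimConfig:
    """One simulated trial.

    ``displacement_m`` is signed: positive = pull (+z toward the face).
    ``onset_latency_s`` is the true motion onset measured from stimulus
    onset (i.e. the trial's true RT in seconds).
    """

    onset_latency_s: float = 0.35
    stroke_duration_s: float = 0.4
    displacement_m: float = 0.25
    stim_onset_s: float = 0.5  # fixation cross precedes the image by 500 ms
    sample_rate_hz: float = 100.0
    sampling_jitter_sd_s: float = 0.001
    noise_sd_ms2: float = 0.05
    gravity: tuple[float, float, float] = STANDARD_GRAVITY
    has_linear_accelerometer: bool = False
    include_return_stroke: bool = True
    return_delay_s: float = 0.15
    tail_rest_s: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.stroke_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")
        if self.include_return_stroke and self.displacement_m == 0.0:
            raise ValueError("return stroke with zero displacement is degenerate")
        if self.onset_latency_s < 0 or self.stim_onset_s < 0:
            raise ValueError("latencies must be non-negative")


def simulate_trace(
    cfg: TraceSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[SensorTrace, dict]:
    """Simulate one trial; returns the trace and its ground-truth row.

    The same seed (via ``cfg.seed`` or an identically seeded generator)
    yields a bit-identical trace.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t_on = cfg.stim_onset_s + cfg.onset_latency_s
    T = cfg.stroke_duration_s
    t_return = t_on + T + cfg.return_delay_s
    # cover the full 2 s response window even for quick movements
    t_total = max(
        t_return + (T if cfg.include_return_stroke else 0.0) + cfg.tail_rest_s,
        cfg.stim_onset_s + 2.0 + 0.1,
    )
    n = int(round(t_total * cfg.sample_rate_hz)) + 1
    t = np.arange(n) / cfg.sample_rate_hz
    if cfg.sampling_jitter_sd_s > 0:
        jitter = rng.normal(0.0, cfg.sampling_jitter_sd_s, size=n)
        # clipping jitter below half a step keeps timestamps strictly increasing
        np.clip(jitter, -0.45 / cfg.sample_rate_hz, 0.45 / cfg.sample_rate_hz, out=jitter)
        t = t + jitter
        t[0] = max(t[0], 0.0)

    az = min_jerk_acceleration(t, cfg.displacement_m, T, t_on)
    if cfg.include_return_stroke:
        az = az + min_jerk_acceleration(t, -cfg.displacement_m, T, t_return)
    acc = np.zeros((n, 3))
    acc[:, 2] = az
    acc += np.asarray(cfg.gravity if not cfg.has_linear_accelerometer else (0, 0, 0))
    if cfg.noise_sd_ms2 > 0:
        acc = acc + rng.normal(0.0, cfg.noise_sd_ms2, size=(n, 3))
    trace = SensorTrace(
        t=t, acc=acc, has_linear_accelerometer=cfg.has_linear_accelerometer
    )
    truth = {
        "stim_onset_s": cfg.stim_onset_s,
        "true_onset_s": t_on,
        "true_rt_ms": cfg.onset_latency_s * 1000.0,
        "true_displacement_m": abs(cfg.displacement_m),
        "true_direction": "pull" if cfg.displacement_m > 0 else "push",
        "true_peak_acc_ms2": min_jerk_peak_acceleration(cfg.displacement_m, T),
        "stroke_duration_s": T,
    }
    return trace, truth


@dataclass
class ExperimentSimConfig:
    """A whole cohort.

    Defaults mirror the task design: 4 categories x 2 directions x 20
    trials (10 images per category per half, each shown twice per
    direction) and a cohort of 71 participants.  The congruency effect is
    split +/- effect/2 so that direction and category margins stay flat and
    the interaction carries the planted effect.
    """

    n_participants: int = 71
    trials_per_cell: int = 20
    base_rt_ms: float = 650.0
    congruency_effect_ms: float = 30.0
    rt_noise_sd_ms: float = 100.0
    rt_participant_sd_ms: float = 60.0
    min_rt_ms: float = 50.0
    base_displacement_m: float = 0.25
    arousal_distance_gain: float = 0.3
    displacement_noise_frac: float = 0.1
    stroke_duration_range_s: tuple[float, float] = (0.3, 0.5)
    sample_rate_hz: float = 100.0
    sampling_jitter_sd_s: float = 0.001
    noise_sd_ms2: float = 0.05
    rating_sd: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_cell < 1:
            raise ValueError("counts must be >= 1")
        if not np.isfinite(self.congruency_effect_ms):
            raise ValueError("congruency effect must be finite")

    def distance_multiplier(self, category: str) -> float:
        arousal = RATING_MEANS[category]["arousal"]
        return 1.0 + self.arousal_distance_gain * (arousal - 50.0) / 50.0


@dataclass
class ExperimentGroundTruth:
    trials: pd.DataFrame  # one row per trial
    planted: dict  # planted condition-level parameters


def _planted_rt_ms(
    cfg: ExperimentSimConfig,
    rng: np.random.Generator,
    category: str,
    direction: str,
    participant_offset: float,
) -> float:
    congruent = (category, direction) in CONGRUENT_PAIRS
    adj = -cfg.congruency_effect_ms / 2 if congruent else cfg.congruency_effect_ms / 2
    rt = cfg.base_rt_ms + participant_offset + adj + rng.normal(0.0, cfg.rt_noise_sd_ms)
    return max(cfg.min_rt_ms, rt)


def _trial_plan(
    cfg: ExperimentSimConfig, rng: np.random.Generator, pid: str
) -> list[dict]:
    """Randomized trial list for one participant: category x direction x images."""
    n_images = max(1, cfg.trials_per_cell // 2)
    reps = int(np.ceil(cfg.trials_per_cell / n_images))
    plan = []
    for category in CATEGORIES:
        for direction in DIRECTIONS:
            stims = [
                f"{category}_{i:02d}" for i in range(n_images) for _ in range(reps)
            ][: cfg.trials_per_cell]
            for s in stims:
                plan.append(
                    {"category": category, "instructed_direction": direction, "stimulus_id": s}
                )
    order = rng.permutation(len(plan))
    out = []
    for k, idx in enumerate(order):
        row = dict(plan[idx])
        row["participant_id"] = pid
        row["trial"] = k
        row["block"] = 1 + (2 * k) // len(plan)  # two halves
        out.append(row)
    return out


def _ratings_for(
    cfg: ExperimentSimConfig, rng: np.random.Generator, pid: str
) -> list[RatingRecord]:
    n_images = max(1, cfg.trials_per_cell // 2)
    out = []
    for category in CATEGORIES:
        means = RATING_MEANS[category]
        for i in range(n_images):
            vals = {
                k: float(np.clip(rng.normal(means[k], cfg.rating_sd), 0.0, 100.0))
                for k in ("valence", "arousal", "wanting")
            }
            out.append(
                RatingRecord(
                    participant_id=pid,
                    stimulus_id=f"{category}_{i:02d}",
                    category=category,
                    **vals,
                )
            )
    return out


def simulate_experiment(
    cfg: Optional[ExperimentSimConfig] = None,
    emit: Literal["traces", "metrics"] = "traces",
    rng: Optional[np.random.Generator] = None,
) -> tuple[list, ExperimentGroundTruth]:
    """Simulate a cohort.

    emit="traces"
        Full sensor traces: returns ``(list[Session], ExperimentGroundTruth)``.
        Every session passes :func:`mobileaat.io.validate_session`.
    emit="metrics"
        The same planted per-trial quantities as ready-made
        :class:`~mobileaat.records.TrialMetrics`-shaped DataFrame rows
        (RT, distance, direction), skipping trace synthesis.  This exercises
        the QC + statistics layers at replication scale; trace-level
        recovery is validated separately.
    """
    cfg = cfg or ExperimentSimConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sessions: list[Session] = []
    metric_rows: list[dict] = []
    truth_rows: list[dict] = []
    for p in range(cfg.n_participants):
        pid = f"P{p:03d}"
        offset = rng.normal(0.0, cfg.rt_participant_sd_ms)
        plan = _trial_plan(cfg, rng, pid)
        trials: list[TrialRecord] = []
        for row in plan:
            category = row["category"]
            direction = row["instructed_direction"]
            rt_ms = _planted_rt_ms(cfg, rng, category, direction, offset)
            D = (
                cfg.base_displacement_m
                * cfg.distance_multiplier(category)
                * (1.0 + rng.normal(0.0, cfg.displacement_noise_frac))
            )
            D = max(0.05, D)
            signed_D = D if direction == "pull" else -D
            T = rng.uniform(*cfg.stroke_duration_range_s)
            truth = {
                **row,
                "true_rt_ms": rt_ms,
                "true_displacement_m": D,
                "true_direction": direction,
                "stroke_duration_s": T,
                "congruent": (category, direction) in CONGRUENT_PAIRS,
            }
            if emit == "traces":
                tcfg = TraceSimConfig(
                    onset_latency_s=rt_ms / 1000.0,
                    stroke_duration_s=T,
                    displacement_m=signed_D,
                    sample_rate_hz=cfg.sample_rate_hz,
                    sampling_jitter_sd_s=cfg.sampling_jitter_sd_s,
                    noise_sd_ms2=cfg.noise_sd_ms2,
                )
                trace, tr_truth = simulate_trace(tcfg, rng)
                truth["true_onset_s"] = tr_truth["true_onset_s"]
                truth["true_peak_acc_ms2"] = tr_truth["true_peak_acc_ms2"]
                trials.append(
                    TrialRecord(
                        participant_id=pid,
                        block=row["block"],
                        stimulus_id=row["stimulus_id"],
                        category=category,
                        instructed_direction=direction,
                        stim_onset=tcfg.stim_onset_s,
                        trace=trace,
                        trial=row["trial"],
                    )
                )
            else:
                metric_rows.append(
                    {
                        "participant_id": pid,
                        "trial": row["trial"],
                        "block": row["block"],
                        "stimulus_id": row["stimulus_id"],
                        "category": category,
                        "instructed_direction": direction,
                        "rt_ms": rt_ms,
                        "distance_m": D,
                        "peak_acc_ms2": min_jerk_peak_acceleration(D, T),
                        "observed_direction": direction,
                        "status": "valid",
                    }
                )
            truth_rows.append(truth)
        if emit == "traces":
            sessions.append(
                Session(
                    participant_id=pid,
                    trials=trials,
                    ratings=_ratings_for(cfg, rng, pid),
                    neophobia_score=float(np.clip(rng.normal(32.0, 9.0), 10.0, 70.0)),
                )
            )
    truth = ExperimentGroundTruth(
        trials=pd.DataFrame(truth_rows),
        planted={
            "base_rt_ms": cfg.base_rt_ms,
            "congruency_effect_ms": cfg.congruency_effect_ms,
            "base_displacement_m": cfg.base_displacement_m,
            "distance_multiplier": {
                c: cfg.distance_multiplier(c) for c in CATEGORIES
            },
            "rating_means": RATING_MEANS,
        },
    )
    if emit == "traces":
        return sessions, truth
    return metric_rows, truth


def simulate_metrics_frame(
    cfg: Optional[ExperimentSimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, ExperimentGroundTruth]:
    """Planted per-trial metrics as a DataFrame (fast path, no traces)."""
    rows, truth = simulate_experiment(cfg, emit="metrics", rng=rng)
    from .io import METRICS_COLUMNS

    return pd.DataFrame(rows, columns=METRICS_COLUMNS), truth


def recovery_report(
    truth: pd.DataFrame,
    metrics: pd.DataFrame,
    rt_tolerance_ms: float = 20.0,
    distance_tolerance_frac: float = 0.10,
) -> pd.DataFrame:
    """Bias, RMSE and tolerance coverage of pipeline outputs vs ground truth.

    Joined on (participant_id, trial); only trials the pipeline marked
    ``valid`` enter the error statistics.
    """
    merged = truth.merge(
        metrics, on=["participant_id", "trial"], suffixes=("_true", "")
    )
    if merged.empty:
        raise ValueError("no matching (participant_id, trial) rows between inputs")
    ok = merged[merged.status == "valid"]
    rows = []
    rt_err = ok.rt_ms - ok.true_rt_ms
    rows.append(
        {
            "quantity": "rt_ms",
            "n": len(ok),
            "bias": rt_err.mean(),
            "rmse": float(np.sqrt((rt_err**2).mean())),
            "coverage": float((rt_err.abs() <= rt_tolerance_ms).mean()),
            "tolerance": rt_tolerance_ms,
        }
    )
    d_rel = (ok.distance_m - ok.true_displacement_m) / ok.true_displacement_m
    rows.append(
        {
            "quantity": "distance_m",
            "n": len(ok),
            "bias": float((ok.distance_m - ok.true_displacement_m).mean()),
            "rmse": float(
                np.sqrt(((ok.distance_m - ok.true_displacement_m) ** 2).mean())
            ),
            "coverage": float((d_rel.abs() <= distance_tolerance_frac).mean()),
            "tolerance": distance_tolerance_frac,
        }
    )
    return pd.DataFrame(rows)
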