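"""Reading, writing and validating session and metrics files.

Canonical on-disk format is one JSON file per session (traces are ragged, so
they nest naturally); a long-format CSV dialect is accepted for
interoperability.  Derived per-trial metrics go to a flat CSV.

Time is stored in seconds relative to trial start; the stimulus onset is on
the same clock.  The device axis convention is declared in the file header
(``+z_toward_face``): positive z displacement means the phone moved toward
the participant's face, i.e. a pull.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import (
    AXIS_CONVENTION,
    TRIAL_STATUSES,
    RatingRecord,
    Session,
    SensorTrace,
    TrialMetrics,
    TrialRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Fixed column order of the metrics CSV.  ``trial`` (the index of the trial
#: within its session) is included so rows can be matched back to raw trials
#: and simulator ground truth.
METRICS_COLUMNS = [
    "participant_id",
    "trial",
    "block",
    "stimulus_id",
    "category",
    "instructed_direction",
    "rt_ms",
    "distance_m",
    "peak_acc_ms2",
    "observed_direction",
    "status",
]

_TRIAL_FIELDS = ("block", "stimulus_id", "category", "instructed_direction", "stim_onset", "trace")
_TRACE_FIELDS = ("t", "acc")


class SchemaError(ValueError):
    """A session file violates the documented schema."""


# ---------------------------------------------------------------------------
# Session JSON
# ---------------------------------------------------------------------------

def session_to_dict(session: Session) -> dict:
    trials = []
    for rec in session.trials:
        tr = rec.trace
        trials.append(
            {
                "block": rec.block,
                "stimulus_id": rec.stimulus_id,
                "category": rec.category,
                "instructed_direction": rec.instructed_direction,
                "stim_onset": rec.stim_onset,
                "trace": {
                    "t": tr.t.tolist(),
                    "acc": tr.acc.tolist(),
                    "gyro": None if tr.gyro is None else tr.gyro.tolist(),
                    "has_linear_accelerometer": tr.has_linear_accelerometer,
                },
            }
        )
    ratings = None
    if session.ratings is not None:
        ratings = [
            {
                "stimulus_id": r.stimulus_id,
                "category": r.category,
                "valence": r.valence,
                "arousal": r.arousal,
                "wanting": r.wanting,
            }
            for r in session.ratings
        ]
    return {
        "participant_id": session.participant_id,
        "axis_convention": AXIS_CONVENTION,
        "trials": trials,
        "ratings": ratings,
        "neophobia_score": session.neophobia_score,
    }


def write_session(session: Session, path: PathLike) -> None:
    """Write a session as canonical JSON (deterministic byte layout)."""
    with open(path, "w") as fh:
        json.dump(session_to_dict(session), fh, indent=1)
        fh.write("\n")


def _trace_from_dict(d: dict, trial_index: int) -> SensorTrace:
    for name in _TRACE_FIELDS:
        if name not in d:
            raise SchemaError(f"trial {trial_index}: trace missing field {name!r}")
    gyro = d.get("gyro")
    return SensorTrace(
        t=np.asarray(d["t"], dtype=float),
        acc=np.asarray(d["acc"], dtype=float),
        gyro=None if gyro is None else np.asarray(gyro, dtype=float),
        has_linear_accelerometer=bool(d.get("has_linear_accelerometer", False)),
    )


def session_from_dict(data: dict) -> Session:
    if "participant_id" not in data:
        raise SchemaError("session missing field 'participant_id'")
    pid = str(data["participant_id"])
    convention = data.get("axis_convention", AXIS_CONVENTION)
    if convention != AXIS_CONVENTION:
        raise SchemaError(
            f"unsupported axis_convention {convention!r}; expected {AXIS_CONVENTION!r}"
        )
    trials: list[TrialRecord] = []
    for i, td in enumerate(data.get("trials", [])):
        for name in _TRIAL_FIELDS:
            if name not in td:
                raise SchemaError(f"trial {i}: missing field {name!r}")
        trace = _trace_from_dict(td["trace"], i)
        if np.any(np.diff(trace.t) <= 0):
            logger.warning(
                "participant %s trial %d: non-monotone timestamps; trace rejected",
                pid,
                i,
            )
            continue
        trials.append(
            TrialRecord(
                participant_id=pid,
                block=int(td["block"]),
                stimulus_id=str(td["stimulus_id"]),
                category=str(td["category"]),
                instructed_direction=str(td["instructed_direction"]),
                stim_onset=float(td["stim_onset"]),
                trace=trace,
                trial=i,
            )
        )
    ratings = None
    if data.get("ratings") is not None:
        ratings = [
            RatingRecord(
                participant_id=pid,
                stimulus_id=str(r["stimulus_id"]),
                category=str(r["category"]),
                valence=float(r["valence"]),
                arousal=float(r["arousal"]),
                wanting=float(r["wanting"]),
            )
            for r in data["ratings"]
        ]
    neo = data.get("neophobia_score")
    return Session(
        participant_id=pid,
        trials=trials,
        ratings=ratings,
        neophobia_score=None if neo is None else float(neo),
    )


# ---------------------------------------------------------------------------
# Session CSV (long format)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "row_type",
    "participant_id",
    "trial",
    "block",
    "stimulus_id",
    "category",
    "instructed_direction",
    "stim_onset",
    "has_linear_accelerometer",
    "t",
    "ax",
    "ay",
    "az",
    "gx",
    "gy",
    "gz",
    "valence",
    "arousal",
    "wanting",
    "neophobia_score",
    "axis_convention",
]


def write_session_csv(session: Session, path: PathLike) -> None:
    """Long-format CSV: one ``sample`` row per sensor sample, plus ``rating``
    and ``meta`` rows.  Equivalent in content to the JSON format."""
    rows: list[dict] = []
    rows.append(
        {
            "row_type": "meta",
            "participant_id": session.participant_id,
            "neophobia_score": session.neophobia_score,
            "axis_convention": AXIS_CONVENTION,
        }
    )
    for i, rec in enumerate(session.trials):
        tr = rec.trace
        has_gyro = tr.gyro is not None
        for k in range(tr.n_samples):
            row = {
                "row_type": "sample",
                "participant_id": session.participant_id,
                "trial": i,
                "block": rec.block,
                "stimulus_id": rec.stimulus_id,
                "category": rec.category,
                "instructed_direction": rec.instructed_direction,
                "stim_onset": rec.stim_onset,
                "has_linear_accelerometer": tr.has_linear_accelerometer,
                "t": tr.t[k],
                "ax": tr.acc[k, 0],
                "ay": tr.acc[k, 1],
                "az": tr.acc[k, 2],
            }
            if has_gyro:
                row.update(gx=tr.gyro[k, 0], gy=tr.gyro[k, 1], gz=tr.gyro[k, 2])
            rows.append(row)
    for r in session.ratings or []:
        rows.append(
            {
                "row_type": "rating",
                "participant_id": session.participant_id,
                "stimulus_id": r.stimulus_id,
                "category": r.category,
                "valence": r.valence,
                "arousal": r.arousal,
                "wanting": r.wanting,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _read_session_csv(path: PathLike) -> Session:
    df = pd.read_csv(path)
    missing = {"row_type", "participant_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"session CSV missing columns {sorted(missing)}")
    meta = df[df.row_type == "meta"]
    pid = str(meta.participant_id.iloc[0]) if len(meta) else str(df.participant_id.iloc[0])
    neo = None
    if len(meta) and pd.notna(meta.neophobia_score.iloc[0]):
        neo = float(meta.neophobia_score.iloc[0])

    trials: list[TrialRecord] = []
    samples = df[df.row_type == "sample"]
    for name in ("trial", "stim_onset", "t", "ax", "ay", "az"):
        if name not in df.columns or (len(samples) and samples[name].isna().any()):
            raise SchemaError(f"sample rows missing field {name!r}")
    for trial_idx, g in samples.groupby("trial", sort=True):
        i = int(trial_idx)
        has_gyro = "gx" in g.columns and g["gx"].notna().all() and len(g) > 0
        t = g["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            logger.warning(
                "participant %s trial %d: non-monotone timestamps; trace rejected", pid, i
            )
            continue
        trace = SensorTrace(
            t=t,
            acc=g[["ax", "ay", "az"]].to_numpy(dtype=float),
            gyro=g[["gx", "gy", "gz"]].to_numpy(dtype=float) if has_gyro else None,
            has_linear_accelerometer=bool(g["has_linear_accelerometer"].iloc[0]),
        )
        trials.append(
            TrialRecord(
                participant_id=pid,
                block=int(g["block"].iloc[0]),
                stimulus_id=str(g["stimulus_id"].iloc[0]),
                category=str(g["category"].iloc[0]),
                instructed_direction=str(g["instructed_direction"].iloc[0]),
                stim_onset=float(g["stim_onset"].iloc[0]),
                trace=trace,
                trial=i,
            )
        )
    ratings = None
    rat = df[df.row_type == "rating"]
    if len(rat):
        ratings = [
            RatingRecord(
                participant_id=pid,
                stimulus_id=str(r.stimulus_id),
                category=str(r.category),
                valence=float(r.valence),
                arousal=float(r.arousal),
                wanting=float(r.wanting),
            )
            for r in rat.itertuples()
        ]
    return Session(participant_id=pid, trials=trials, ratings=ratings, neophobia_score=neo)


def read_session(path: PathLike, format: Optional[str] = None) -> Session:
    """Read a session file.

    Parameters
    ----------
    path : path
        Session file (JSON or long-format CSV).
    format : {"json", "csv"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
        return session_from_dict(data)
    if format == "csv":
        return _read_session_csv(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------

def metrics_to_frame(metrics: Sequence[TrialMetrics]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": m.participant_id,
            "trial": m.trial,
            "block": m.block,
            "stimulus_id": m.stimulus_id,
            "category": m.category,
            "instructed_direction": m.instructed_direction,
            "rt_ms": m.rt_ms,
            "distance_m": m.distance_m,
            "peak_acc_ms2": m.peak_acc_ms2,
            "observed_direction": m.observed_direction,
            "status": m.status,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_table(metrics: Sequence[TrialMetrics], path: PathLike) -> None:
    """One row per trial; the status enum is serialized as its lowercase token."""
    if not len(metrics):
        raise ValueError("metrics must be non-empty")
    metrics_to_frame(metrics).to_csv(path, index=False)


def read_metrics_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"metrics CSV missing columns {sorted(missing)}")
    bad = set(df.status.unique()) - set(TRIAL_STATUSES)
    if bad:
        raise SchemaError(f"metrics CSV contains unknown statuses {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    trial_index: Optional[int]  # None = session-level
    message: str

    def __str__(self) -> str:
        where = "session" if self.trial_index is None else f"trial {self.trial_index}"
        return f"{where}: {self.message}"


@dataclass
class ValidationReport:
    participant_id: str
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return f"session {self.participant_id}: OK"
        lines = [f"session {self.participant_id}: {len(self.violations)} problem(s)"]
        lines += [f"  {v}" for v in self.violations]
        return "\n".join(lines)


def validate_session(session: Session) -> ValidationReport:
    """Report every invariant violation; an empty report means processable."""
    report = ValidationReport(participant_id=session.participant_id)
    if not session.trials:
        report.violations.append(Violation(None, "session contains no trials"))
    for i, rec in enumerate(session.trials):
        if rec.participant_id != session.participant_id:
            report.violations.append(
                Violation(i, f"participant_id {rec.participant_id!r} differs from session")
            )
        for msg in rec.problems():
            report.violations.append(Violation(i, msg))
    for r in session.ratings or []:
        for msg in r.problems():
            report.violations.append(Violation(None, f"rating {r.stimulus_id}: {msg}"))
    if session.neophobia_score is not None and not (
        10.0 <= session.neophobia_score <= 70.0
    ):
        report.violations.append(
            Violation(None, f"neophobia_score {session.neophobia_score} outside [10, 70]")
        )
    return report
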