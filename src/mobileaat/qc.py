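"""Trial- and participant-level validity rules, and the cohort QC report.

Rules (task constants, configurable for sensitivity analyses only):

* RT < 200 ms -> ``too_fast`` and the whole trial is discarded (an onset that
  quick cannot be a response to the stimulus).
* RT > 2000 ms, or no threshold crossing at all -> ``no_reaction``.
* A participant with less than 75% valid trials is an incomplete dataset and
  is excluded; exactly 75% is still included.

Trials whose observed movement direction contradicts the instruction remain
valid but are flagged — direction errors are reported, not excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import TRIAL_STATUSES, TrialMetrics


@dataclass
class QCConfig:
    rt_min_ms: float = 200.0
    rt_max_ms: float = 2000.0
    participant_min_valid_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.rt_min_ms < self.rt_max_ms):
            raise ValueError("need 0 < rt_min_ms < rt_max_ms")
        if not (0 < self.participant_min_valid_fraction <= 1):
            raise ValueError("participant_min_valid_fraction must be in (0, 1]")


@dataclass
class ParticipantQC:
    participant_id: str
    n_trials: int
    n_valid: int
    status_counts: dict[str, int]
    included: bool
    n_direction_mismatch: int = 0

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_trials


def classify_trial(metrics: TrialMetrics, cfg: Optional[QCConfig] = None) -> TrialMetrics:
    """Return a copy with the final QC status applied.

    A kinematically detected onset whose RT falls outside [rt_min, rt_max]
    is reclassified; per the invariant that ``rt_ms`` accompanies only
    ``valid`` / ``too_fast`` trials, a late onset loses its RT.
    """
    cfg = cfg or QCConfig()
    if metrics.status in ("no_reaction", "no_onset"):
        return metrics
    rt = metrics.rt_ms
    if rt is None:
        return replace(metrics, status="no_onset")
    if rt < cfg.rt_min_ms:
        return replace(metrics, status="too_fast")
    if rt > cfg.rt_max_ms:
        return replace(metrics, status="no_reaction", rt_ms=None)
    return replace(metrics, status="valid")


def classify_trials(
    metrics: Sequence[TrialMetrics], cfg: Optional[QCConfig] = None
) -> list[TrialMetrics]:
    cfg = cfg or QCConfig()
    return [classify_trial(m, cfg) for m in metrics]


def participant_validity(
    metrics: Sequence[TrialMetrics], cfg: Optional[QCConfig] = None
) -> ParticipantQC:
    """Per-participant validity accounting; inclusion at >= the 75% criterion."""
    cfg = cfg or QCConfig()
    if not len(metrics):
        raise ValueError("participant has no trials")
    counts = {s: 0 for s in TRIAL_STATUSES}
    mismatches = 0
    for m in metrics:
        counts[m.status] += 1
        if m.direction_mismatch:
            mismatches += 1
    n_valid = counts["valid"]
    included = n_valid / len(metrics) >= cfg.participant_min_valid_fraction
    return ParticipantQC(
        participant_id=metrics[0].participant_id,
        n_trials=len(metrics),
        n_valid=n_valid,
        status_counts=counts,
        included=included,
        n_direction_mismatch=mismatches,
    )


def valid_trials(metrics: Iterable[TrialMetrics]) -> list[TrialMetrics]:
    return [m for m in metrics if m.status == "valid"]


@dataclass
class CohortQCReport:
    per_participant: pd.DataFrame
    n_participants: int
    n_included: int
    n_excluded_valid_fraction: int
    totals: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_included": self.n_included,
            "n_excluded_valid_fraction": self.n_excluded_valid_fraction,
            "status_totals": self.totals,
        }


def qc_report(
    per_participant_metrics: Mapping[str, Sequence[TrialMetrics]],
    cfg: Optional[QCConfig] = None,
) -> CohortQCReport:
    """Cohort-level accounting: per-participant table plus exclusion totals."""
    cfg = cfg or QCConfig()
    if not per_participant_metrics:
        raise ValueError("no sessions supplied")
    rows = []
    totals = {s: 0 for s in TRIAL_STATUSES}
    for pid, ms in per_participant_metrics.items():
        qc = participant_validity(list(ms), cfg)
        for s, c in qc.status_counts.items():
            totals[s] += c
        row = {
            "participant_id": pid,
            "n_trials": qc.n_trials,
            "n_valid": qc.n_valid,
            "valid_fraction": qc.valid_fraction,
            "included": qc.included,
            "n_direction_mismatch": qc.n_direction_mismatch,
        }
        row.update({f"n_{s}": qc.status_counts[s] for s in TRIAL_STATUSES})
        rows.append(row)
    df = pd.DataFrame(rows)
    n_included = int(df.included.sum())
    return CohortQCReport(
        per_participant=df,
        n_participants=len(df),
        n_included=n_included,
        n_excluded_valid_fraction=len(df) - n_included,
        totals=totals,
    )
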