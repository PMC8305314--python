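"""Participant-level aggregation and the study's statistical layer.

The unit of analysis is the participant x stimulus-category x movement-
direction cell mean over valid trials.  From the cells:

* RT score = mean RT(push) - mean RT(pull) per category.  Pulling faster
  than pushing gives a positive score, read as approach motivation.
* Distance score = mean of the pull and push distances per category
  (distance effects in this task are direction-independent, so the two are
  averaged rather than differenced).

Tests mirror the classical repertoire for this design: 2x2 repeated-
measures ANOVA (category x direction) on RT and on distance, Wilcoxon
signed-rank tests on paired rating means, and Pearson correlations between
scores and ratings.  All tests are two-sided at alpha = 0.05.

The 2x2 within-subject ANOVA is computed from explicit sums of squares
(each effect has 1 numerator df; with two-level factors sphericity holds
trivially, and each F(1, n-1) equals the squared paired t on the
corresponding within-participant contrast).  The Wilcoxon statistic is
W = min(W+, W-) with mid-ranks for ties and zero differences dropped; the
null distribution is enumerated exactly for n <= 15 and approximated by a
continuity-corrected normal (with tie correction) above.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import TrialMetrics

ALPHA = 0.05

#: n pairs up to which the Wilcoxon null is enumerated exactly.
WILCOXON_EXACT_MAX_N = 15


# ---------------------------------------------------------------------------
# Aggregation and scores
# ---------------------------------------------------------------------------

def _as_frame(trials: Union[pd.DataFrame, Sequence[TrialMetrics]]) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    from .io import metrics_to_frame

    return metrics_to_frame(list(trials))


def aggregate_cells(trials: Union[pd.DataFrame, Sequence[TrialMetrics]]) -> pd.DataFrame:
    """Mean RT and distance per (participant, category, direction) over valid trials.

    Cells with no valid trial are absent from the output (the participant
    may then drop from paired tests by listwise deletion).
    """
    df = _as_frame(trials)
    valid = df[df.status == "valid"]
    if valid.empty:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "category",
                "direction",
                "mean_rt_ms",
                "mean_distance_m",
                "n_valid",
            ]
        )
    cells = (
        valid.groupby(
            ["participant_id", "category", "instructed_direction"], sort=True
        )
        .agg(
            mean_rt_ms=("rt_ms", "mean"),
            mean_distance_m=("distance_m", "mean"),
            n_valid=("rt_ms", "size"),
        )
        .reset_index()
        .rename(columns={"instructed_direction": "direction"})
    )
    return cells


def _paired_directions(cells: pd.DataFrame) -> pd.DataFrame:
    wide = cells.pivot_table(
        index=["participant_id", "category"],
        columns="direction",
        values=["mean_rt_ms", "mean_distance_m"],
        aggfunc="first",
    )
    full_cols = pd.MultiIndex.from_product(
        [["mean_rt_ms", "mean_distance_m"], ["pull", "push"]]
    )
    wide = wide.reindex(columns=full_cols)
    # keep only rows with both directions present
    return wide.dropna(subset=[("mean_rt_ms", "pull"), ("mean_rt_ms", "push")])


def rt_score(cells: pd.DataFrame) -> pd.DataFrame:
    """push - pull mean RT (ms) per participant x category; positive = approach."""
    wide = _paired_directions(cells)
    out = wide.index.to_frame(index=False)
    out["rt_score_ms"] = (
        wide[("mean_rt_ms", "push")] - wide[("mean_rt_ms", "pull")]
    ).to_numpy()
    return out


def distance_score(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean of pull and push distances (m) per participant x category."""
    wide = _paired_directions(cells)
    out = wide.index.to_frame(index=False)
    out["distance_score_m"] = (
        (wide[("mean_distance_m", "pull")] + wide[("mean_distance_m", "push")]) / 2.0
    ).to_numpy()
    return out


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    direction: EffectResult
    category: EffectResult
    interaction: EffectResult
    n: int  # participants entering (complete cells)
    n_dropped: int  # participants removed by listwise deletion

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("direction", "category", "interaction"):
            e: EffectResult = getattr(self, name)
            rows.append(
                {
                    "effect": name,
                    "F": e.F,
                    "df1": e.df1,
                    "df2": e.df2,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "n": self.n,
                }
            )
        return pd.DataFrame(rows)


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    category_col: str = "category",
    direction_col: str = "direction",
) -> AnovaResult:
    """Two-way fully within-subject ANOVA for a 2 (category) x 2 (direction) design.

    Computed from explicit sums of squares; every effect is tested against
    its own effect-by-subject interaction with df (1, n-1).  Participants
    missing any of the four cells are removed listwise.
    """
    cats = sorted(data[category_col].unique())
    dirs = sorted(data[direction_col].unique())
    if len(cats) != 2 or len(dirs) != 2:
        raise ValueError(
            f"need exactly 2 levels per factor, got {cats} x {dirs}"
        )
    wide = data.pivot_table(
        index=subject, columns=[category_col, direction_col], values=dv, aggfunc="mean"
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    n = len(complete)
    if n < 3:
        raise ValueError(f"RM-ANOVA needs >= 3 complete participants, got {n}")

    # y[i, a, b]: subject x category-level x direction-level
    y = np.empty((n, 2, 2))
    for ai, a in enumerate(cats):
        for bi, b in enumerate(dirs):
            y[:, ai, bi] = complete[(a, b)].to_numpy()

    grand = y.mean()
    subj = y.mean(axis=(1, 2))  # per-subject means
    mean_a = y.mean(axis=(0, 2))  # category-level means
    mean_b = y.mean(axis=(0, 1))  # direction-level means
    mean_ab = y.mean(axis=0)  # cell means
    mean_ia = y.mean(axis=2)  # subject x category
    mean_ib = y.mean(axis=1)  # subject x direction

    ss_a = 2 * n * np.sum((mean_a - grand) ** 2)
    ss_b = 2 * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum(
        (mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_as = 2 * np.sum(
        (mean_ia - subj[:, None] - mean_a[None, :] + grand) ** 2
    )
    ss_bs = 2 * np.sum(
        (mean_ib - subj[:, None] - mean_b[None, :] + grand) ** 2
    )
    resid = (
        y
        - mean_ia[:, :, None]
        - mean_ib[:, None, :]
        - mean_ab[None, :, :]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        + subj[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df2 = n - 1

    def effect(ss_eff: float, ss_err: float) -> EffectResult:
        if ss_err == 0.0:
            # no residual variability: F undefined; report 0/inf convention
            f = 0.0 if ss_eff == 0.0 else np.inf
            p = 1.0 if ss_eff == 0.0 else 0.0
        else:
            f = (ss_eff / 1) / (ss_err / df2)
            p = float(sps.f.sf(f, 1, df2))
        denom = ss_eff + ss_err
        eta = ss_eff / denom if denom > 0 else 0.0
        return EffectResult(F=float(f), df1=1, df2=df2, p=p, partial_eta_sq=float(eta))

    return AnovaResult(
        direction=effect(ss_b, ss_bs),
        category=effect(ss_a, ss_as),
        interaction=effect(ss_ab, ss_abs),
        n=n,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    W: float  # min(W+, W-)
    p: float  # two-sided
    n_used: int  # pairs after dropping zero differences
    method: str  # "exact" or "normal"
    degenerate: bool = False  # all differences were zero


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum via the null distribution of W+.

    Mid-ranks may be half-integers; working in doubled units keeps the
    distribution on an integer lattice.  The null is symmetric about
    sum(ranks)/2, so the two-sided p mass is |W+ - mu| >= observed.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    # distribution of 2*W+ by polynomial multiplication
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    mu = total / 2.0
    dev = abs(2 * w_plus - mu)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    x: Iterable[float], y: Iterable[float]
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; ties get mid-ranks; W = min(W+, W-).
    Exact enumeration of the null for n <= 15 pairs, continuity-corrected
    normal approximation (with tie correction) beyond.
    """
    d = np.asarray(list(x), dtype=float) - np.asarray(list(y), dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(W=0.0, p=1.0, n_used=0, method="exact", degenerate=True)
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(W=w, p=min(1.0, p), n_used=n, method="exact")
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    z = (w - mu + 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return WilcoxonResult(W=w, p=p, n_used=n, method="normal")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class PearsonResult:
    r: float
    r_squared: float
    p: float
    n: int


def pearson_r(x: Iterable[float], y: Iterable[float]) -> PearsonResult:
    """Product-moment correlation with two-sided p from the t distribution."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r=r, r_squared=r * r, p=float(res.pvalue), n=x.size)


# ---------------------------------------------------------------------------
# Study-level convenience analysis
# ---------------------------------------------------------------------------

#: The two planned category contrasts: strong (palatable vs unpalatable) and
#: subtle (dutch vs asian).
CATEGORY_PAIRS = (("palatable", "unpalatable"), ("dutch", "asian"))


def rating_means(ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean valence / arousal / wanting per participant x category."""
    return (
        ratings.groupby(["participant_id", "category"], sort=True)[
            ["valence", "arousal", "wanting"]
        ]
        .mean()
        .reset_index()
    )


def standard_analysis(
    cells: pd.DataFrame,
    ratings: Optional[pd.DataFrame] = None,
    neophobia: Optional[pd.DataFrame] = None,
) -> dict[str, pd.DataFrame]:
    """Run the full planned analysis; returns tidy tables keyed by kind.

    ``anova``: RT and distance, per category pair, three effects each.
    ``wilcoxon``: rating contrasts between the paired categories.
    ``correlations``: RT score vs valence/wanting, distance score vs arousal,
    and neophobia vs ratings / RT score for Asian images, where inputs allow.
    """
    out: dict[str, pd.DataFrame] = {}
    anova_rows = []
    for measure, dv in (("rt", "mean_rt_ms"), ("distance", "mean_distance_m")):
        for pair in CATEGORY_PAIRS:
            sub = cells[cells.category.isin(pair)]
            try:
                res = rm_anova_2x2(sub, dv=dv)
            except ValueError:
                continue
            tbl = res.to_frame()
            tbl.insert(0, "measure", measure)
            tbl.insert(1, "pair", "_vs_".join(pair))
            anova_rows.append(tbl)
    if anova_rows:
        out["anova"] = pd.concat(anova_rows, ignore_index=True)

    scores = rt_score(cells).merge(distance_score(cells), on=["participant_id", "category"])
    out["scores"] = scores

    if ratings is not None and len(ratings):
        rmeans = rating_means(ratings)
        wil_rows = []
        for var in ("valence", "arousal", "wanting"):
            for pair in CATEGORY_PAIRS:
                wide = rmeans.pivot_table(
                    index="participant_id", columns="category", values=var
                )
                if not set(pair) <= set(wide.columns):
                    continue
                paired = wide[list(pair)].dropna()
                try:
                    res = wilcoxon_signed_rank(paired[pair[0]], paired[pair[1]])
                except ValueError:
                    continue
                wil_rows.append(
                    {
                        "measure": var,
                        "pair": "_vs_".join(pair),
                        "W": res.W,
                        "p": res.p,
                        "n": res.n_used,
                        "method": res.method,
                    }
                )
        if wil_rows:
            out["wilcoxon"] = pd.DataFrame(wil_rows)

        corr_rows = []
        merged = scores.merge(rmeans, on=["participant_id", "category"])
        for cat in sorted(merged.category.unique()):
            sub = merged[merged.category == cat]
            for score_col, rating_col in (
                ("rt_score_ms", "valence"),
                ("rt_score_ms", "wanting"),
                ("distance_score_m", "arousal"),
            ):
                try:
                    res = pearson_r(sub[score_col], sub[rating_col])
                except ValueError:
                    continue
                corr_rows.append(
                    {
                        "category": cat,
                        "x": score_col,
                        "y": rating_col,
                        "r": res.r,
                        "r_squared": res.r_squared,
                        "p": res.p,
                        "n": res.n,
                    }
                )
        if neophobia is not None and len(neophobia):
            asian = merged[merged.category == "asian"].merge(
                neophobia, on="participant_id"
            )
            for col in ("rt_score_ms", "valence", "wanting"):
                try:
                    res = pearson_r(asian["neophobia_score"], asian[col])
                except ValueError:
                    continue
                corr_rows.append(
                    {
                        "category": "asian",
                        "x": "neophobia_score",
                        "y": col,
                        "r": res.r,
                        "r_squared": res.r_squared,
                        "p": res.p,
                        "n": res.n,
                    }
                )
        if corr_rows:
            out["correlations"] = pd.DataFrame(corr_rows)
    return out
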