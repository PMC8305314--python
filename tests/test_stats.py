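"""Aggregation, congruency scores, RM-ANOVA, Wilcoxon and Pearson kernels."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mobileaat as m
from mobileaat.records import TrialMetrics
from mobileaat.stats import (
    aggregate_cells,
    distance_score,
    pearson_r,
    rm_anova_2x2,
    rt_score,
    wilcoxon_signed_rank,
)


def trial(pid, cat, direction, rt, dist=0.2, status="valid", i=0):
    return TrialMetrics(pid, i, 1, f"s{i}", cat, direction, rt, dist, 5.0, direction, status)


def cells_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "category", "direction", "mean_rt_ms",
                       "mean_distance_m", "n_valid"]
    )


class TestAggregation:
    def test_cell_mean_over_valid_trials(self):
        ms = [trial("P0", "palatable", "pull", 400.0, i=0),
              trial("P0", "palatable", "pull", 600.0, i=1),
              trial("P0", "palatable", "pull", 100.0, status="too_fast", i=2)]
        cells = aggregate_cells(ms)
        assert len(cells) == 1
        assert cells.mean_rt_ms.iloc[0] == pytest.approx(500.0)
        assert cells.n_valid.iloc[0] == 2

    def test_empty_cell_absent(self):
        ms = [trial("P0", "palatable", "pull", 500.0),
              trial("P0", "asian", "push", None, status="no_reaction", i=1)]
        cells = aggregate_cells(ms)
        assert set(zip(cells.category, cells.direction)) == {("palatable", "pull")}

    def test_recovers_planted_cell_means_within_se(self, rng):
        cfg = m.ExperimentSimConfig(n_participants=1, trials_per_cell=50,
                                    congruency_effect_ms=0.0, rt_participant_sd_ms=0.0)
        df, truth = m.simulate_metrics_frame(cfg, rng=rng)
        cells = aggregate_cells(df)
        se = cfg.rt_noise_sd_ms / np.sqrt(cfg.trials_per_cell)
        for row in cells.itertuples():
            assert abs(row.mean_rt_ms - cfg.base_rt_ms) < 4 * se


class TestScores:
    def test_rt_score_is_push_minus_pull(self):
        cells = cells_frame([
            ("P0", "palatable", "pull", 650.0, 0.30, 10),
            ("P0", "palatable", "push", 700.0, 0.20, 10),
        ])
        out = rt_score(cells)
        assert out.rt_score_ms.iloc[0] == pytest.approx(50.0)  # approach
        out2 = distance_score(cells)
        assert out2.distance_score_m.iloc[0] == pytest.approx(0.25)

    def test_rt_score_antisymmetric_distance_symmetric(self):
        base = cells_frame([
            ("P0", "asian", "pull", 700.0, 0.30, 10),
            ("P0", "asian", "push", 650.0, 0.20, 10),
        ])
        swapped = base.copy()
        swapped.direction = swapped.direction.map({"pull": "push", "push": "pull"})
        assert rt_score(base).rt_score_ms.iloc[0] == pytest.approx(
            -rt_score(swapped).rt_score_ms.iloc[0]
        )
        assert distance_score(base).distance_score_m.iloc[0] == pytest.approx(
            distance_score(swapped).distance_score_m.iloc[0]
        )

    def test_missing_direction_dropped(self):
        cells = cells_frame([("P0", "asian", "pull", 700.0, 0.3, 10)])
        assert len(rt_score(cells)) == 0


def random_2x2(rng, n=8, sd=50.0):
    rows = []
    for p in range(n):
        for c in ("a", "b"):
            for d in ("pull", "push"):
                rows.append(dict(participant_id=f"P{p:02d}", category=c, direction=d,
                                 mean_rt_ms=rng.normal(600, sd)))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        rows = [dict(participant_id=f"P{p}", category=c, direction=d,
                     mean_rt_ms=600.0 + 10 * p)
                for p in range(5) for c in ("a", "b") for d in ("pull", "push")]
        res = rm_anova_2x2(pd.DataFrame(rows), "mean_rt_ms")
        for eff in (res.direction, res.category, res.interaction):
            assert eff.F == 0.0 and eff.p == 1.0

    def test_interaction_equals_squared_paired_t(self, rng):
        for _ in range(20):
            df = random_2x2(rng)
            res = rm_anova_2x2(df, "mean_rt_ms")
            wide = df.pivot_table(index="participant_id",
                                  columns=["category", "direction"], values="mean_rt_ms")
            dod = (wide[("a", "push")] - wide[("a", "pull")]) - (
                wide[("b", "push")] - wide[("b", "pull")]
            )
            t = sps.ttest_1samp(dod, 0.0)
            assert res.interaction.F == pytest.approx(t.statistic**2, rel=1e-8)
            assert res.interaction.p == pytest.approx(t.pvalue, rel=1e-8)

    def test_main_effects_equal_squared_paired_t(self, rng):
        df = random_2x2(rng)
        res = rm_anova_2x2(df, "mean_rt_ms")
        wide = df.pivot_table(index="participant_id",
                              columns=["category", "direction"], values="mean_rt_ms")
        d_dir = (wide[("a", "push")] + wide[("b", "push")]) / 2 - (
            wide[("a", "pull")] + wide[("b", "pull")]) / 2
        t = sps.ttest_1samp(d_dir, 0.0)
        assert res.direction.F == pytest.approx(t.statistic**2, rel=1e-8)

    def test_matches_brute_force_sums_of_squares(self):
        """n=4 hand table vs an independent from-scratch SS computation."""
        rng = np.random.default_rng(99)
        df = random_2x2(rng, n=4)
        res = rm_anova_2x2(df, "mean_rt_ms")
        y = np.empty((4, 2, 2))
        pids = sorted(df.participant_id.unique())
        for i, p in enumerate(pids):
            for ai, c in enumerate(("a", "b")):
                for bi, d in enumerate(("pull", "push")):
                    y[i, ai, bi] = df[(df.participant_id == p) & (df.category == c)
                                      & (df.direction == d)].mean_rt_ms.iloc[0]
        # brute-force: loop-based textbook sums of squares
        gm = y.mean()
        ss_cat = sum(4.0 * (y[:, a, :].mean() - gm) ** 2 for a in range(2)) * 2
        ss_cat_err = 0.0
        for i in range(4):
            for a in range(2):
                ss_cat_err += 2 * (y[i, a, :].mean() - y[i].mean() - y[:, a, :].mean() + gm) ** 2
        f_cat = ss_cat / (ss_cat_err / 3)
        assert res.category.F == pytest.approx(f_cat, rel=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = random_2x2(rng, n=10)
        res = rm_anova_2x2(df, "mean_rt_ms")
        table = pg.rm_anova(data=df, dv="mean_rt_ms", within=["category", "direction"],
                            subject="participant_id", detailed=True).set_index("Source")
        assert res.category.F == pytest.approx(table.loc["category", "F"], rel=1e-6)
        assert res.direction.F == pytest.approx(table.loc["direction", "F"], rel=1e-6)
        assert res.interaction.F == pytest.approx(
            table.loc["category * direction", "F"], rel=1e-6)

    def test_ss_decomposition_conserves_cell_variability(self, rng):
        """Effect + error SS reproduce the total within-subject variability."""
        df = random_2x2(rng)
        wide = df.pivot_table(index="participant_id",
                              columns=["category", "direction"], values="mean_rt_ms")
        y = wide.to_numpy().reshape(-1, 2, 2)
        total_within = ((y - y.mean(axis=(1, 2), keepdims=True)) ** 2).sum()
        # the three orthonormal within-subject contrasts (direction, category,
        # interaction) partition each subject's cell variability exactly
        z_dir = (y[:, :, 1] - y[:, :, 0]).mean(axis=1)
        z_cat = (y[:, 1, :] - y[:, 0, :]).mean(axis=1)
        z_int = ((y[:, 1, 1] - y[:, 1, 0]) - (y[:, 0, 1] - y[:, 0, 0])) / 2.0
        ss_sum = np.sum(z_dir**2) + np.sum(z_cat**2) + np.sum(z_int**2)
        assert ss_sum == pytest.approx(total_within, rel=1e-8)

    def test_listwise_deletion_and_min_n(self):
        rng = np.random.default_rng(3)
        df = random_2x2(rng, n=4)
        df = df.drop(df[(df.participant_id == "P00") & (df.direction == "pull")
                        & (df.category == "a")].index)
        res = rm_anova_2x2(df, "mean_rt_ms")
        assert res.n == 3 and res.n_dropped == 1
        tiny = random_2x2(rng, n=2)
        with pytest.raises(ValueError, match=">= 3"):
            rm_anova_2x2(tiny, "mean_rt_ms")

    def test_permuting_participants_changes_nothing(self, rng):
        df = random_2x2(rng)
        res1 = rm_anova_2x2(df, "mean_rt_ms")
        res2 = rm_anova_2x2(df.sample(frac=1.0, random_state=1), "mean_rt_ms")
        assert res1.interaction.F == pytest.approx(res2.interaction.F, rel=1e-12)


class TestWilcoxon:
    def test_rank_arithmetic_example(self):
        res = wilcoxon_signed_rank([1, -2, 3, 4, 5], np.zeros(5))
        assert res.W == 2.0  # W- is the rank of |-2|

    def test_all_positive_exact_p(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], np.zeros(5))
        assert res.W == 0.0
        assert res.p == pytest.approx(2 / 32)

    def test_exact_p_equals_brute_force_enumeration(self, rng):
        """All n <= 10 against direct enumeration of every sign pattern."""
        for n in range(5, 11):
            for _ in range(3):
                d = np.round(rng.normal(0, 2, n), 1)
                d[d == 0] = 0.5
                res = wilcoxon_signed_rank(d, np.zeros(n))
                ranks = sps.rankdata(np.abs(d))
                mu = ranks.sum() / 2
                obs = ranks[d > 0].sum()
                count = sum(
                    abs(sum(r for r, s in zip(ranks, signs) if s > 0) - mu)
                    >= abs(obs - mu) - 1e-9
                    for signs in itertools.product((1, -1), repeat=n)
                )
                assert res.p == pytest.approx(count / 2**n, abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        for n in (6, 9, 12):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            res = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, mode="exact")
            assert res.W == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approximation_converges_to_exact(self, rng):
        """At n=15 the continuity-corrected normal p is within 5% of exact."""
        rel_errors = []
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 15)
            d = d[d != 0]
            res_exact = wilcoxon_signed_rank(d, np.zeros_like(d))
            mu = res_exact.n_used * (res_exact.n_used + 1) / 4
            var = res_exact.n_used * (res_exact.n_used + 1) * (2 * res_exact.n_used + 1) / 24
            z = (res_exact.W - mu + 0.5) / np.sqrt(var)
            p_norm = min(1.0, 2 * sps.norm.cdf(z))
            if res_exact.p > 0.01:
                rel_errors.append(abs(p_norm - res_exact.p) / res_exact.p)
        assert np.median(rel_errors) < 0.05

    def test_zero_differences_dropped_and_degenerate_flagged(self):
        res = wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)
        assert res.degenerate
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank([1, 2, 3, 1, 1], [1, 1, 1, 1, 1])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_after_centering(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_r(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_hand_table_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        res = pearson_r(x, y)
        assert res.r == pytest.approx(r_direct, rel=1e-12)
        t = r_direct * np.sqrt(3 / (1 - r_direct**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 3), rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_standard_analysis_tables(rng):
    cfg = m.ExperimentSimConfig(n_participants=12, trials_per_cell=6, seed=21)
    sessions, _ = m.simulate_experiment(cfg)
    all_metrics = []
    ratings = []
    neo = []
    for s in sessions:
        all_metrics += m.classify_trials(m.process_session(s.trials))
        ratings += [
            dict(participant_id=r.participant_id, stimulus_id=r.stimulus_id,
                 category=r.category, valence=r.valence, arousal=r.arousal,
                 wanting=r.wanting)
            for r in s.ratings
        ]
        neo.append(dict(participant_id=s.participant_id,
                        neophobia_score=s.neophobia_score))
    cells = aggregate_cells(all_metrics)
    tables = m.standard_analysis(cells, ratings=pd.DataFrame(ratings),
                                 neophobia=pd.DataFrame(neo))
    assert {"anova", "scores", "wilcoxon", "correlations"} <= set(tables)
    anova = tables["anova"]
    assert set(anova.pair) == {"palatable_vs_unpalatable", "dutch_vs_asian"}
    assert set(anova.measure) == {"rt", "distance"}
    assert (anova.F >= 0).all()
    # ratings were planted with strong category contrasts: Wilcoxon should
    # flag valence differences in both pairs
    wil = tables["wilcoxon"].set_index(["measure", "pair"])
    assert wil.loc[("valence", "palatable_vs_unpalatable"), "p"] < 0.05
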