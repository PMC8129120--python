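"""Spine-level aggregation statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spinescale.nd import classify_spines
from spinescale.spine_stats import (
    assign_quintiles,
    classify_dendrites,
    cohens_d,
    correlate_performance_nd,
    nd_table,
    per_mouse_class_test,
    performance_stats,
    proportionality_test,
    quintile_profile,
    ratio_baseline_correlation,
    select_max_spines,
    turnover_balance_test,
    turnover_counts,
)

from conftest import random_nd_frame


def _label(df, threshold=0.15):
    df = df.copy()
    df["label"] = classify_spines(df["nd"].to_numpy(), threshold)
    return df


class TestPerMouseClassification:
    def test_matches_bruteforce_percentages(self):
        rng = np.random.default_rng(3)
        df = _label(random_nd_frame(rng))
        summary = per_mouse_class_test(df)
        for _, row in summary.per_mouse.iterrows():
            grp = df[df.mouse_id == row.mouse_id]
            n_up = sum(
                1 for v in grp.nd if v > 0.15
            )
            n_down = sum(1 for v in grp.nd if v < -0.15)
            assert row.pct_up == pytest.approx(100 * n_up / len(grp))
            assert row.pct_down == pytest.approx(100 * n_down / len(grp))
            assert row.pct_up + row.pct_down + row.pct_no_change == pytest.approx(100)

    def test_identical_up_down_gives_t_zero(self):
        rows = []
        for m in range(4):
            for nd in [0.3, -0.3, 0.0, 0.0]:
                rows.append(
                    {
                        "mouse_id": f"M{m}",
                        "condition": "S",
                        "nd": nd,
                    }
                )
        df = _label(pd.DataFrame(rows))
        summary = per_mouse_class_test(df)
        assert summary.t_stat == pytest.approx(0.0, abs=1e-12)
        assert summary.p_value == pytest.approx(1.0)

    def test_sleep_downscaling_detected(self, default_cohort):
        table, _, _ = default_cohort
        summary = per_mouse_class_test(nd_table(table, ("T-24", "T-17")))
        assert summary.mean_pct_down > summary.mean_pct_up
        assert summary.p_value < 0.05


class TestDendriteClassification:
    def test_majority_rule_and_tie(self):
        rows = []
        for i, nd in enumerate([0.3, 0.3, 0.3, -0.3]):
            rows.append(
                {"mouse_id": "M0", "dendrite_id": "d_up", "spine_id": f"a{i}", "nd": nd}
            )
        for i, nd in enumerate([0.3, 0.3, -0.3, -0.3]):
            rows.append(
                {"mouse_id": "M0", "dendrite_id": "d_tie", "spine_id": f"b{i}", "nd": nd}
            )
        dend = classify_dendrites(_label(pd.DataFrame(rows)))
        labels = dend.set_index("dendrite_id")["label"]
        assert labels["d_up"] == "up"
        assert labels["d_tie"] == "same"

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(4)
        df = _label(random_nd_frame(rng))
        dend = classify_dendrites(df)
        for _, row in dend.iterrows():
            grp = df[(df.mouse_id == row.mouse_id) & (df.dendrite_id == row.dendrite_id)]
            n_up = sum(1 for v in grp.nd if v > 0.15)
            n_down = sum(1 for v in grp.nd if v < -0.15)
            expect = "up" if n_up > n_down else ("down" if n_down > n_up else "same")
            assert row.label == expect


class TestQuintiles:
    @staticmethod
    def _table_from_intensities(intensities):
        rows = []
        for tp in ("T-24", "T-17"):
            for i, x in enumerate(intensities):
                rows.append(
                    {
                        "mouse_id": "M0",
                        "condition": "S",
                        "dendrite_id": "d0",
                        "spine_id": f"s{i:03d}",
                        "timepoint": tp,
                        "spine_sep": x,
                        "present": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_ten_spines_split_in_pairs(self):
        q = assign_quintiles(self._table_from_intensities(range(1, 11)))
        by_spine = q.sort_values("rank_stat")["quintile"].tolist()
        assert by_spine == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_ties_broken_by_input_order(self):
        q = assign_quintiles(self._table_from_intensities([2.0] * 10))
        assert q["quintile"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    @pytest.mark.parametrize("n", [5, 7, 23, 104])
    def test_sizes_differ_by_at_most_one(self, n):
        rng = np.random.default_rng(n)
        q = assign_quintiles(self._table_from_intensities(rng.lognormal(0, 1, n)))
        sizes = q["quintile"].value_counts()
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_spines_raises(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            assign_quintiles(self._table_from_intensities([1, 2, 3, 4]))

    def test_profile_matches_bruteforce(self, default_cohort):
        table, _, _ = default_cohort
        nd = nd_table(table, ("T-24", "T-17"))
        quintiles = assign_quintiles(table, ("T-24", "T-17"))
        prof = quintile_profile(nd, quintiles)
        assert prof["n_spines"].sum() == len(
            nd.merge(quintiles[["mouse_id", "spine_id"]], on=["mouse_id", "spine_id"])
        )
        merged = nd.merge(
            quintiles[["mouse_id", "spine_id", "quintile"]],
            on=["mouse_id", "spine_id"],
        )
        for q in range(1, 6):
            sub = merged[merged.quintile == q]
            assert prof.loc[prof.quintile == q, "mean_nd"].iloc[0] == pytest.approx(
                sub.nd.mean()
            )


class TestMaxSpines:
    def test_empty_when_no_change(self, static_config):
        from spinescale import generate_cohort

        table, _, _ = generate_cohort(static_config, seed=2)
        part = select_max_spines(table)
        assert part.n_max == 0
        assert part.pct_overall == 0.0

    def test_flags_match_bruteforce(self, default_cohort):
        table, _, _ = default_cohort
        part = select_max_spines(table, threshold=0.2)
        nd = nd_table(table, ("T-24", "T0"), threshold=0.2)
        expected = set(nd.loc[nd.nd > 0.2, "spine_id"])
        assert set(part.flags.loc[part.flags.is_max, "spine_id"]) == expected
        assert part.n_total == len(nd)

    def test_require_both_baselines_is_stricter(self, default_cohort):
        table, _, _ = default_cohort
        loose = select_max_spines(table)
        strict = select_max_spines(table, require_both_baselines=True)
        assert strict.n_max <= loose.n_max
        strict_set = set(strict.flags.loc[strict.flags.is_max, "spine_id"])
        loose_set = set(loose.flags.loc[loose.flags.is_max, "spine_id"])
        assert strict_set <= loose_set


class TestProportionality:
    def test_exact_proportional_change(self):
        rng = np.random.default_rng(8)
        df = random_nd_frame(rng)
        df["x_post"] = 1.5 * df["x_pre"]
        res = proportionality_test(df)
        assert np.allclose(res.per_mouse["value"], 1.0)

    def test_per_mouse_r_matches_formula(self):
        rng = np.random.default_rng(9)
        df = random_nd_frame(rng)
        res = proportionality_test(df)
        for _, row in res.per_mouse.iterrows():
            grp = df[df.mouse_id == row.mouse_id]
            r, _ = stats.pearsonr(grp.x_pre, grp.x_post - grp.x_pre)
            assert row.value == pytest.approx(r)

    def test_null_calibration(self):
        # baseline-independent change: the one-sample t across mice should
        # reject at roughly the nominal rate
        rejections = 0
        n_sims = 300
        for i in range(n_sims):
            rng = np.random.default_rng(10_000 + i)
            rows = []
            for m in range(8):
                x = rng.lognormal(0, 0.5, 30)
                delta = rng.normal(0, 0.3, 30)  # independent of baseline
                rows.extend(
                    {"mouse_id": f"M{m}", "x_pre": xv, "x_post": xv + dv}
                    for xv, dv in zip(x, np.clip(delta, -x + 1e-6, None))
                )
            res = proportionality_test(pd.DataFrame(rows))
            rejections += res.p_value < 0.05
        rate = rejections / n_sims
        assert 0.02 <= rate <= 0.09


class TestRatioBaselineCorrelation:
    def test_constant_ratio_gives_nan_free_zero(self):
        rng = np.random.default_rng(12)
        x = rng.lognormal(0, 0.5, 400)
        r = ratio_baseline_correlation(x, 2.0 * x, mode="naive")
        assert abs(r) < 1e-6 or np.isnan(r)

    @staticmethod
    def _artifact_only(sd, n_rep=40):
        # latent baseline with measurement noise; the post/pre ratio is
        # independent of the latent baseline, so any correlation is artifact
        rng = np.random.default_rng(13)
        naive_rs, split_rs = [], []
        for i in range(n_rep):
            latent = rng.lognormal(0.5, 0.4, 600)
            x_pre = np.clip(latent + rng.normal(0, sd, 600), 1e-3, None)
            x_post = latent * rng.lognormal(0, 0.2, 600)
            naive_rs.append(ratio_baseline_correlation(x_pre, x_post, "naive"))
            split_rs.append(
                ratio_baseline_correlation(
                    x_pre, x_post, "split_half", measurement_sd=sd, seed=i
                )
            )
        return np.mean(naive_rs), np.mean(split_rs)

    def test_mechanical_artifact_reduced_by_split_half(self):
        # split-half removes the first-order shared-noise coupling; a small
        # second-order (denominator-convexity) residual remains and shrinks
        # with the noise level
        naive, split = self._artifact_only(sd=0.3)
        assert naive < -0.15
        assert abs(split) < 0.6 * abs(naive)
        naive_mild, split_mild = self._artifact_only(sd=0.1)
        assert abs(split_mild) < 0.04
        assert abs(split_mild) < abs(split)


class TestTurnoverBalance:
    def test_perfect_balance_p_one(self):
        stat, p = turnover_balance_test([3, 1, 2, 0], [3, 1, 2, 0])
        assert p == 1.0

    def test_matches_exact_enumeration(self):
        # small worked example checked against the exact signed-rank null
        formed = np.array([5, 3, 8, 2, 6, 4])
        eliminated = np.array([2, 4, 3, 1, 2, 1])
        stat, p = turnover_balance_test(formed, eliminated)
        ref = stats.wilcoxon(formed, eliminated, zero_method="wilcox", method="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_type_one_error_near_nominal(self):
        rejections = 0
        n_sims = 2000
        rng = np.random.default_rng(77)
        for _ in range(n_sims):
            diffs = rng.normal(0, 1, 10)
            formed = 10 + diffs
            eliminated = np.full(10, 10.0)
            _, p = turnover_balance_test(formed, eliminated)
            rejections += p < 0.05
        rate = rejections / n_sims
        # exact test is conservative at n=10 (discrete null)
        assert rate <= 0.07

    def test_counts_on_cohort_balanced(self, default_cohort):
        table, _, _ = default_cohort
        counts = turnover_counts(table)
        stat, p = turnover_balance_test(
            counts.groupby("mouse_id")["formed"].sum(),
            counts.groupby("mouse_id")["eliminated"].sum(),
        )
        assert p > 0.05


class TestPerformance:
    def test_hand_computed_t_on_toy_table(self):
        rows = []
        s_vals = [10.0, 11.0, 12.0, 9.0, 10.5, 11.5]
        sd_vals = [8.0, 9.0, 7.5, 8.5, 9.5, 8.0]
        for i, v in enumerate(s_vals + sd_vals):
            cond = "S" if i < 6 else "SD"
            for session in (1, 2):
                for trial in range(1, 21):
                    rows.append(
                        {
                            "mouse_id": f"M{i}",
                            "condition": cond,
                            "session": session,
                            "trial": trial,
                            "fall_speed": v,
                        }
                    )
        res = performance_stats(pd.DataFrame(rows))
        t_ref, p_ref = stats.ttest_ind(s_vals, sd_vals)
        assert res.session2_onset_between["t"] == pytest.approx(t_ref)
        assert res.session2_onset_between["p"] == pytest.approx(p_ref)
        assert res.session2_onset_between["d"] == pytest.approx(
            cohens_d(np.array(s_vals), np.array(sd_vals))
        )
        # within-session speeds constant -> no improvement
        assert res.session1_within["p"] == pytest.approx(1.0)

    def test_session1_learning_detected(self, default_cohort):
        _, perf, _ = default_cohort
        res = performance_stats(perf)
        assert res.session1_within["t"] > 0
        assert res.session1_within["p"] < 0.01


class TestPerformanceNdCorrelation:
    def test_perfect_anticorrelation(self):
        nd = np.linspace(-0.1, 0.1, 8)
        speed = 10 - 50 * nd
        r, p = correlate_performance_nd(nd, speed)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-10)

    def test_fisher_z_matches_formula(self):
        rng = np.random.default_rng(21)
        nd = rng.normal(0, 0.05, 12)
        speed = 12 - 30 * nd + rng.normal(0, 1, 12)
        r, p = correlate_performance_nd(nd, speed)
        r_ref = np.corrcoef(nd, speed)[0, 1]
        p_ref = 2 * stats.norm.sf(abs(np.arctanh(r_ref)) * np.sqrt(12 - 3))
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref)

    def test_requires_four_mice(self):
        with pytest.raises(ValueError):
            correlate_performance_nd([0.1, 0.2, 0.3], [1, 2, 3])
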