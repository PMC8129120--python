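"""Generative sleep-mechanism models: construction identities, summary
statistics, the relative-error objective and the fitting machinery."""

import numpy as np
import pytest
from scipy import stats

from spinescale.mechanism import (
    PotentiationParams,
    SummaryStats,
    WakeNoiseParams,
    WakePool,
    apply_intervening_wake,
    apply_sleep_potentiation,
    compare_models,
    fit_model,
    quintile_labels,
    simulate_baseline,
    simulate_dataset,
    summarize,
    total_relative_error,
)


class TestSimulateBaseline:
    def test_moment_matching_at_large_n(self):
        x = simulate_baseline(100_000, 1.0, 1.0, seed=0)
        se_mean = x.std(ddof=1) / np.sqrt(len(x))
        assert x.mean() == pytest.approx(1.0, abs=3 * se_mean)
        # variance of a lognormal variance estimate is heavy-tailed; allow a
        # generous but still informative band
        assert x.var(ddof=1) == pytest.approx(1.0, rel=0.15)

    def test_log_is_normal(self):
        x = simulate_baseline(100_000, 2.0, 0.8, seed=1)
        assert abs(stats.skew(np.log(x))) < 0.05

    def test_small_variance_concentrates_at_mean(self):
        x = simulate_baseline(10_000, 3.0, 1e-8, seed=2)
        assert np.allclose(x, 3.0, atol=1e-3)

    def test_rejects_non_positive_moments(self):
        with pytest.raises(ValueError):
            simulate_baseline(10, -1.0, 1.0)
        with pytest.raises(ValueError):
            simulate_baseline(10, 1.0, 0.0)


class TestPotentiationMechanism:
    def test_zero_params_identity(self):
        pre = simulate_baseline(2000, 1.0, 0.5, seed=3)
        params = PotentiationParams(0.0, 1.5, 0.0, 0.7, 0.0)
        post = apply_sleep_potentiation(pre, params, seed=4)
        assert np.array_equal(post, pre)
        s = summarize(pre, post)
        assert s.corr_pre_post == pytest.approx(1.0)
        assert s.prop_up == 0.0 and s.prop_down == 0.0

    def test_pure_downscaling_all_cross_threshold(self):
        pre = simulate_baseline(2000, 1.0, 0.5, seed=5)
        params = PotentiationParams(0.0, 1.5, 1.0, 0.6, 0.0)
        post = apply_sleep_potentiation(pre, params, seed=6)
        nd = (post - pre) / (post + pre)
        assert np.allclose(nd, (0.6 - 1) / (0.6 + 1))
        assert summarize(pre, post).prop_down == 1.0

    def test_log_changes_take_three_values_with_matching_frequencies(self):
        pre = simulate_baseline(20_000, 1.0, 0.5, seed=7)
        params = PotentiationParams(0.2, 1.8, 0.3, 0.55, 0.0)
        post = apply_sleep_potentiation(pre, params, seed=8)
        logdiff = np.round(np.log(post) - np.log(pre), 10)
        values, counts = np.unique(logdiff, return_counts=True)
        assert len(values) == 3
        freq = dict(zip(values, counts / len(pre)))
        assert freq[np.round(np.log(0.55), 10)] == pytest.approx(0.3, abs=0.02)
        assert freq[0.0] == pytest.approx(0.5, abs=0.02)
        assert freq[np.round(np.log(1.8), 10)] == pytest.approx(0.2, abs=0.02)

    def test_rejects_overlapping_proportions(self):
        with pytest.raises(ValueError):
            PotentiationParams(0.6, 1.5, 0.6, 0.7, 0.1).validate()


class TestWakeMechanism:
    @staticmethod
    def _pool(rng, n=500):
        pre = simulate_baseline(n, 1.0, 0.3, rng)
        post = pre * np.exp(rng.normal(0.02, 0.2, n))
        return WakePool.from_intensities(pre, post)

    def test_all_zero_params_identity(self):
        rng = np.random.default_rng(9)
        pool = self._pool(rng)
        pre = simulate_baseline(1000, 1.0, 0.3, rng)
        params = WakeNoiseParams(0.0, 0.7, 0.0, 0.0)
        post = apply_intervening_wake(pre, params, pool, seed=10)
        assert np.array_equal(post, pre)

    def test_degenerate_constant_pool(self):
        pool = WakePool(deltas=[np.full(10, 0.25)] * 5)
        pre = simulate_baseline(500, 1.0, 0.3, seed=11)
        # rescaled to sigma_wake = 0: the wake component vanishes
        post = apply_intervening_wake(
            pre, WakeNoiseParams(0.0, 0.7, 0.0, 0.0), pool, seed=12
        )
        assert np.array_equal(post, pre)
        # rescaling disabled: every spine shifts by exactly the constant
        post_raw = apply_intervening_wake(
            pre, WakeNoiseParams(0.0, 0.7, 0.0, 0.3), pool, seed=12, rescale="raw"
        )
        assert np.allclose(post_raw - pre, 0.25)

    def test_bootstrap_respects_quintile_matching(self):
        # tag each quintile pool with a distinct constant and verify every
        # spine receives its own quintile's tag (raw mode)
        tags = [np.full(20, 0.01 * (q + 1)) for q in range(5)]
        pool = WakePool(deltas=tags)
        pre = simulate_baseline(1000, 1.0, 0.3, seed=13)
        post = apply_intervening_wake(
            pre, WakeNoiseParams(0.0, 0.7, 0.0, 1.0), pool, seed=14, rescale="raw"
        )
        received = post - pre
        labels = quintile_labels(pre)
        for q in range(5):
            assert np.allclose(received[labels == q], 0.01 * (q + 1))

    def test_global_rescale_sets_overall_sd(self):
        rng = np.random.default_rng(15)
        pool = self._pool(rng)
        pre = simulate_baseline(50_000, 1.0, 0.3, rng)
        params = WakeNoiseParams(0.0, 0.7, 0.0, 0.33)
        post = apply_intervening_wake(pre, params, pool, seed=16)
        wake = post - pre
        assert wake.std() == pytest.approx(0.33, rel=0.1)

    def test_empty_quintile_pool_rejected(self):
        with pytest.raises(ValueError):
            WakePool(deltas=[np.array([0.1])] * 4 + [np.array([])])


class TestSummarize:
    def test_identity_and_doubling(self):
        pre = simulate_baseline(1000, 1.0, 0.5, seed=17)
        s = summarize(pre, pre.copy())
        assert s.corr_pre_post == pytest.approx(1.0)
        assert s.prop_up == 0.0 and s.prop_down == 0.0
        s2 = summarize(pre, 2 * pre)
        assert s2.prop_up == 1.0  # ND = 1/3 for every spine

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(18)
        pre = rng.lognormal(0, 0.5, 777)
        post = pre * rng.lognormal(0, 0.3, 777)
        s = summarize(pre, post)
        nd = (post - pre) / (post + pre)
        assert s.mean_post == pytest.approx(post.mean())
        assert s.var_post == pytest.approx(post.var(ddof=1))
        assert s.corr_pre_post == pytest.approx(np.corrcoef(pre, post)[0, 1])
        assert s.prop_up == pytest.approx(np.mean(nd > 0.15))
        assert s.prop_down == pytest.approx(np.mean(nd < -0.15))
        order = np.argsort(pre, kind="stable")
        chunks = np.array_split(order, 5)
        for q, chunk in enumerate(chunks):
            assert s.quintile_prop_up[q] == pytest.approx(np.mean(nd[chunk] > 0.15))
            assert s.quintile_prop_down[q] == pytest.approx(np.mean(nd[chunk] < -0.15))

    def test_quintile_sizes_near_equal(self):
        labels = quintile_labels(np.random.default_rng(19).random(103))
        sizes = np.bincount(labels)
        assert sizes.sum() == 103
        assert sizes.max() - sizes.min() <= 1


class TestRelativeError:
    @staticmethod
    def _stats(**over):
        base = dict(
            mean_post=1.0,
            var_post=0.5,
            corr_pre_post=0.9,
            prop_up=0.1,
            prop_down=0.2,
            quintile_prop_up=np.full(5, 0.1),
            quintile_prop_down=np.full(5, 0.2),
            n=1000,
        )
        base.update(over)
        return SummaryStats(**base)

    def test_zero_when_equal(self):
        s = self._stats()
        total, brk = total_relative_error(s, s, "core+quintile")
        assert total == 0.0
        assert all(v == 0 for v in brk.values())

    def test_factor_two_contributes_one(self):
        sim = self._stats(mean_post=2.0)
        total, brk = total_relative_error(sim, self._stats(), "core")
        assert brk["mean_post"] == pytest.approx(-1.0)
        assert total == pytest.approx(1.0)

    def test_breakdown_sums_to_total(self):
        rng = np.random.default_rng(20)
        sim = self._stats(
            mean_post=1.1, var_post=0.45, corr_pre_post=0.85, prop_up=0.12
        )
        total, brk = total_relative_error(sim, self._stats(), "core+quintile")
        assert total == pytest.approx(sum(abs(v) for v in brk.values()))
        signed, brk2 = total_relative_error(
            sim, self._stats(), "core+quintile", signed=True
        )
        assert signed == pytest.approx(sum(brk2.values()))

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            total_relative_error(self._stats(), self._stats(prop_up=0.0), "core")


class TestFitting:
    POT_TRUTH = PotentiationParams(
        p_up=0.15, m_up=1.8, p_down=0.30, m_down=0.45, sigma_ind=0.15
    )
    MOMENTS = (1.0, 0.3)

    def test_argmin_contract_and_recovery_single_replicate(self):
        seed = 42
        pre, post = simulate_dataset(
            "potentiation", self.POT_TRUTH, 1500, self.MOMENTS, seed=seed
        )
        target = summarize(pre, post)
        fit = fit_model("potentiation", target, self.MOMENTS, seed=seed, n_sim=1500)
        # the generating parameters achieve objective 0 under shared draws;
        # the optimizer must never return anything worse than what it saw
        assert fit.total_error <= 0.05
        assert abs(fit.params["p_up"] - 0.15) <= 0.03
        assert abs(fit.params["m_up"] - 1.8) / 1.8 <= 0.15

    def test_wake_fit_requires_pool(self):
        target = summarize(*simulate_dataset(
            "potentiation", self.POT_TRUTH, 500, self.MOMENTS, seed=1
        ))
        with pytest.raises(ValueError, match="pool"):
            fit_model("intervening_wake", target, self.MOMENTS, seed=1)

    def test_compare_models_reports_fit_errors_verbatim(self):
        rng = np.random.default_rng(21)
        pool_pre = simulate_baseline(400, 1.0, 0.3, rng)
        pool = WakePool.from_intensities(
            pool_pre, pool_pre * np.exp(rng.normal(0.02, 0.2, 400))
        )
        wake_truth = WakeNoiseParams(0.25, 0.6, 0.08, 0.18)
        pre, post = simulate_dataset(
            "intervening_wake", wake_truth, 1200, self.MOMENTS, pool=pool, seed=33
        )
        target = summarize(pre, post)
        light = dict(de_budget=(1, 25, 10), nelder_mead_maxiter=150)
        fit_pot = fit_model(
            "potentiation", target, self.MOMENTS, seed=33, n_sim=1200, **light
        )
        fit_wake = fit_model(
            "intervening_wake", target, self.MOMENTS, pool=pool, seed=33,
            n_sim=1200, **light
        )
        report = compare_models(fit_pot, fit_wake)
        for fit in (fit_pot, fit_wake):
            m = report["models"][fit.model]
            assert m["total_error"] == fit.total_error
            assert m["params"] == fit.params
        assert report["winner_quintile_error"] in (
            "potentiation", "intervening_wake", "tie",
        )
        # the wake model generated the data and shares the draws: it must fit
        assert report["models"]["intervening_wake"]["quintile_error"] <= (
            report["models"]["potentiation"]["quintile_error"]
        )

    def test_objective_deterministic_under_seed(self):
        pre, post = simulate_dataset(
            "potentiation", self.POT_TRUTH, 800, self.MOMENTS, seed=7
        )
        target = summarize(pre, post)
        light = dict(de_budget=(1, 15, 8), nelder_mead_maxiter=100)
        f1 = fit_model("potentiation", target, self.MOMENTS, seed=7, n_sim=800, **light)
        f2 = fit_model("potentiation", target, self.MOMENTS, seed=7, n_sim=800, **light)
        assert f1.params == f2.params
        assert f1.total_error == f2.total_error
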