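"""Synthetic longitudinal spine cohorts with known ground truth.

The generator emulates the structure of a two-condition longitudinal
two-photon experiment: ~12 mice imaged at five sessions over 48 h, each
contributing a handful of dendrites with tens of spines.  Spine-surface
GluA1 (SEP channel) and spine size (dsRed2 channel) are log-normal at
baseline with a strong spine SEP <-> spine dsRed2 correlation and a weak
spine <-> shaft SEP correlation.  Between sessions, intensities evolve
multiplicatively: sleep downscales a subset of spines, wake upscales a
subset, motor training boosts a "max" subset, and every spine carries
symmetric log-scale biological volatility plus additive measurement noise.
Spine turnover (formation/elimination) is rare and balanced.  Each mouse's
session-2 behavioral performance is linked linearly to its true net
post-training ND.

All randomness flows from a single integer seed; identical (config, seed)
pairs produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    CONDITIONS,
    INTERVALS,
    LEARNING_INTERVAL,
    POST_TRAINING_INTERVAL,
    TIMEPOINTS,
    SynthConfig,
)
from .nd import classify_spines

# coupling of dsRed2 dynamics to SEP dynamics (shared multiplicative factor
# exponent) and the residual dsRed2-specific volatility; spine size tracks
# synaptic strength changes but not perfectly
_DSRED_DYN_COUPLING = 0.8
_DSRED_OWN_LOG_SD = 0.10
_SHAFT_LOG_SD = 0.05
_INTENSITY_FLOOR_FRAC = 1e-6


def lognormal_params(mean: float, var: float) -> tuple[float, float]:
    """(mu, sigma) of the log for a log-normal with given natural-scale
    mean and variance: mu = ln(m^2/sqrt(v + m^2)), sigma^2 = ln(1 + v/m^2)."""
    if mean <= 0 or var <= 0:
        raise ValueError("log-normal moments must be positive")
    mu = np.log(mean**2 / np.sqrt(var + mean**2))
    sigma = np.sqrt(np.log(1.0 + var / mean**2))
    return float(mu), float(sigma)


def log_correlation(r: float, sigma1: float, sigma2: float) -> float:
    """Log-scale correlation producing natural-scale correlation ``r``
    between two log-normals with log-sds sigma1, sigma2.

    Inverts r = (exp(rho*s1*s2) - 1)/sqrt((exp(s1^2)-1)(exp(s2^2)-1)).
    """
    if abs(r) >= 1:
        raise ValueError("target correlation must satisfy |r| < 1")
    arg = 1.0 + r * np.sqrt(np.expm1(sigma1**2) * np.expm1(sigma2**2))
    if arg <= 0:
        raise ValueError("target correlation infeasible for these marginals")
    rho = np.log(arg) / (sigma1 * sigma2)
    if abs(rho) > 1:
        raise ValueError("target correlation infeasible for these marginals")
    return float(rho)


@dataclass
class GroundTruth:
    """Latent state of a generated cohort.

    ``spines`` has one row per spine with its boosted (max) flag, birth/death
    timepoint indices, per-interval applied multiplicative factor and event
    label, noise-free SEP intensities at each timepoint, and the latent
    up/down/no_change label per interval recomputed from the noise-free
    intensities at threshold 0.15.  ``mice`` has one row per mouse with its
    realized wake fractions, true net post-training ND and noise-free
    session-2 onset speed.
    """

    spines: pd.DataFrame
    mice: pd.DataFrame
    config: SynthConfig


def _spine_counts(rng, cfg: SynthConfig, n_dendrites: int) -> np.ndarray:
    mean, sd = cfg.spines_per_dendrite
    counts = np.round(rng.normal(mean, sd, size=n_dendrites)).astype(int)
    return np.clip(counts, 5, None)


def generate_cohort(
    config: SynthConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (SpineTable, PerformanceTable, GroundTruth) for one cohort.

    The SpineTable is long-format with one row per (spine, timepoint);
    absent spines keep their row with ``present=False`` and missing
    intensities.  Deterministic given (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    mu_sep, sg_sep = lognormal_params(*cfg.baseline_lognormal)
    mu_red, sg_red = lognormal_params(*cfg.dsred_lognormal)
    mu_shs, sg_shs = lognormal_params(*cfg.shaft_sep_lognormal)
    mu_shr, sg_shr = lognormal_params(*cfg.shaft_dsred_lognormal)
    rho_red = log_correlation(cfg.dsred_coupling, sg_sep, sg_red)
    rho_shs = log_correlation(cfg.shaft_coupling, sg_sep, sg_shs)
    # shaft SEP couples to dsRed2 only through the spine SEP channel
    corr = np.array(
        [
            [1.0, rho_red, rho_shs],
            [rho_red, 1.0, rho_red * rho_shs],
            [rho_shs, rho_red * rho_shs, 1.0],
        ]
    )
    chol = np.linalg.cholesky(corr)

    n_tp = len(TIMEPOINTS)
    n_iv = len(INTERVALS)
    p_form, p_elim = cfg.turnover
    p_boost, m_boost = cfg.learning_boost
    p_down_base, m_down = cfg.sleep_downscale
    p_up_base, m_up = cfg.wake_upscale

    spine_rows = []
    mouse_rows = []
    mouse_ids = []
    for cond in CONDITIONS:
        for j in range(cfg.n_mice_per_condition):
            mouse_ids.append((f"{cond}{j + 1:02d}", cond))

    for mouse_id, cond in mouse_ids:
        sched = cfg.state_schedule[cond]
        wake = np.clip(
            np.asarray(sched) + rng.normal(0, cfg.wake_fraction_jitter, n_iv), 0, 1
        )
        lo, hi = cfg.dendrites_per_mouse
        n_dend = int(rng.integers(lo, hi + 1))
        counts = _spine_counts(rng, cfg, n_dend)

        mouse_spines = []  # dicts of per-spine latent state
        for d in range(n_dend):
            dendrite_id = f"{mouse_id}_d{d + 1}"
            n0 = counts[d]
            # initial spines, plus spines formed at later sessions
            births = [0] * n0
            for k in range(n_iv):
                n_formed = rng.binomial(n0, p_form)
                births.extend([k + 1] * n_formed)
            for s, birth in enumerate(births):
                z = chol @ rng.standard_normal(3)
                log_sep = mu_sep + sg_sep * z[0]
                if birth > 0:
                    # newly formed spines are small: baseline from the lower
                    # half of the intensity distribution
                    log_sep = mu_sep - abs(sg_sep * z[0])
                mouse_spines.append(
                    {
                        "spine_id": f"{dendrite_id}_s{s + 1:03d}",
                        "dendrite_id": dendrite_id,
                        "birth": birth,
                        "log_sep0": log_sep,
                        "log_red0": mu_red + sg_red * z[1],
                        "log_shs0": mu_shs + sg_shs * z[2],
                        "log_shr0": mu_shr + sg_shr * rng.standard_normal(),
                        "boosted": bool(rng.random() < p_boost),
                        "protected": bool(rng.random() < cfg.learning_protection),
                    }
                )

        p_down = p_down_base * (1.0 - wake)
        p_up = p_up_base * wake

        for sp in mouse_spines:
            death = n_tp  # exclusive: present for t in [birth, death)
            for k in range(sp["birth"], n_iv):
                if rng.random() < p_elim:
                    death = k + 1
                    break
            sp["death"] = death

            log_sep = np.full(n_tp, np.nan)
            log_red = np.full(n_tp, np.nan)
            log_shs = np.full(n_tp, np.nan)
            log_shr = np.full(n_tp, np.nan)
            b = sp["birth"]
            log_sep[b] = sp["log_sep0"]
            log_red[b] = sp["log_red0"]
            log_shs[b] = sp["log_shs0"]
            log_shr[b] = sp["log_shr0"]
            factors = np.ones(n_iv)
            events = np.array(["none"] * n_iv, dtype=object)
            for k in range(n_iv):
                # dynamics are defined on [birth, death); draws are consumed
                # for every interval to keep the stream layout fixed
                u = rng.random()
                vol = rng.normal(0.0, cfg.volatility_log_sd)
                red_own = rng.normal(0.0, _DSRED_OWN_LOG_SD)
                sh_step = rng.normal(0.0, _SHAFT_LOG_SD, 2)
                if not (b <= k < sp["death"] - 1):
                    continue
                factor = 1.0
                # boosted spines can be resistant to post-training sleep
                # downscaling (down-selection spares potentiated synapses)
                resistant = (
                    sp["boosted"]
                    and sp["protected"]
                    and k >= POST_TRAINING_INTERVAL
                )
                if u < p_down[k] and not resistant:
                    factor = m_down
                    events[k] = "down"
                elif u > 1.0 - p_up[k]:
                    factor = m_up
                    events[k] = "up"
                if k == LEARNING_INTERVAL and sp["boosted"]:
                    factor *= m_boost
                factors[k] = factor
                dlog = np.log(factor) + vol
                log_sep[k + 1] = log_sep[k] + dlog
                log_red[k + 1] = log_red[k] + _DSRED_DYN_COUPLING * dlog + red_own
                log_shs[k + 1] = log_shs[k] + sh_step[0]
                log_shr[k + 1] = log_shr[k] + sh_step[1]
            sp["true_sep"] = np.exp(log_sep)
            sp["true_red"] = np.exp(log_red)
            sp["true_shs"] = np.exp(log_shs)
            sp["true_shr"] = np.exp(log_shr)
            sp["factors"] = factors
            sp["events"] = events
            sp["mouse_id"] = mouse_id
            sp["condition"] = cond
        spine_rows.extend(mouse_spines)
        mouse_rows.append(
            {"mouse_id": mouse_id, "condition": cond, "wake_fractions": wake}
        )

    # measured intensities: additive Gaussian noise, floored at a small
    # positive value (intensities are positive by construction)
    floor = _INTENSITY_FLOOR_FRAC * cfg.baseline_lognormal[0]
    table_rows = []
    for sp in spine_rows:
        noise = rng.normal(0.0, cfg.measurement_noise_sd, (4, n_tp))
        for t, tp in enumerate(TIMEPOINTS):
            present = sp["birth"] <= t < sp["death"]
            if present:
                vals = [
                    max(sp["true_sep"][t] + noise[0, t], floor),
                    max(sp["true_red"][t] + noise[1, t], floor),
                    max(sp["true_shs"][t] + noise[2, t], floor),
                    max(sp["true_shr"][t] + noise[3, t], floor),
                ]
            else:
                vals = [np.nan] * 4
            table_rows.append(
                (
                    sp["mouse_id"],
                    sp["condition"],
                    sp["dendrite_id"],
                    sp["spine_id"],
                    tp,
                    *vals,
                    present,
                )
            )
    spine_table = pd.DataFrame(
        table_rows,
        columns=[
            "mouse_id",
            "condition",
            "dendrite_id",
            "spine_id",
            "timepoint",
            "spine_sep",
            "spine_dsred",
            "shaft_sep",
            "shaft_dsred",
            "present",
        ],
    )

    # mouse-level truth: net post-training ND from noise-free intensities
    pre_t, post_t = POST_TRAINING_INTERVAL, POST_TRAINING_INTERVAL + 1
    for mrow in mouse_rows:
        nds = []
        for sp in spine_rows:
            if sp["mouse_id"] != mrow["mouse_id"]:
                continue
            if sp["birth"] <= pre_t and sp["death"] > post_t:
                a, b_ = sp["true_sep"][pre_t], sp["true_sep"][post_t]
                nds.append((b_ - a) / (b_ + a))
        mrow["true_net_nd"] = float(np.mean(nds)) if nds else np.nan

    performance, mouse_truth = _generate_performance(rng, cfg, mouse_rows)

    gt_rows = []
    thr = 0.15
    for sp in spine_rows:
        row = {
            "mouse_id": sp["mouse_id"],
            "condition": sp["condition"],
            "dendrite_id": sp["dendrite_id"],
            "spine_id": sp["spine_id"],
            "boosted": sp["boosted"],
            "birth_timepoint": TIMEPOINTS[sp["birth"]],
            "death_timepoint": (
                TIMEPOINTS[sp["death"]] if sp["death"] < n_tp else ""
            ),
        }
        for k in range(n_iv):
            row[f"factor_iv{k}"] = sp["factors"][k]
            row[f"event_iv{k}"] = sp["events"][k]
            a, b_ = sp["true_sep"][k], sp["true_sep"][k + 1]
            if np.isfinite(a) and np.isfinite(b_):
                row[f"latent_label_iv{k}"] = classify_spines(
                    [(b_ - a) / (b_ + a)], thr
                )[0]
            else:
                row[f"latent_label_iv{k}"] = ""
        for t, tp in enumerate(TIMEPOINTS):
            row[f"true_sep_{tp}"] = sp["true_sep"][t]
        gt_rows.append(row)
    truth = GroundTruth(
        spines=pd.DataFrame(gt_rows), mice=mouse_truth, config=cfg
    )
    return spine_table, performance, truth


def _generate_performance(rng, cfg: SynthConfig, mouse_rows):
    """Complex-wheel fall speeds: 20 trials x 2 sessions per mouse.

    Session 1 shows within-session improvement shared by all mice; each
    mouse's session-2 onset level is a linear function of its true net
    post-training ND, so that mice with a larger net decrease (more negative
    ND) start session 2 faster.
    """
    pm = cfg.performance_model
    n_trials = 20
    session1_gain = 5.0
    session2_gain = 2.0
    trial_sd = 1.5
    nds = np.array([m["true_net_nd"] for m in mouse_rows])
    if pm.noise_sd is not None:
        noise_sd = pm.noise_sd
    else:
        # calibrate so the expected mouse-level correlation between net ND
        # and the measured session-2 onset (mean of 3 noisy trials) hits
        # target_r; the trial-averaging noise counts against the budget
        sd_nd = float(np.std(nds, ddof=1)) if len(nds) > 1 else 0.0
        r = abs(pm.target_r)
        if r <= 0 or sd_nd == 0:
            noise_sd = 1.0
        else:
            total_noise_var = (pm.slope * sd_nd) ** 2 * (1.0 / r**2 - 1.0)
            noise_sd = float(
                np.sqrt(max(total_noise_var - trial_sd**2 / 3.0, 0.0))
            )

    rows = []
    for mrow in mouse_rows:
        base1 = 6.0 + rng.normal(0, 0.8)
        onset2 = pm.intercept + pm.slope * mrow["true_net_nd"]
        mrow["true_session2_onset"] = onset2
        onset2_obs = onset2 + rng.normal(0, noise_sd)
        for session, (base, gain) in enumerate(
            [(base1, session1_gain), (onset2_obs, session2_gain)], start=1
        ):
            for trial in range(1, n_trials + 1):
                speed = base + gain * (trial - 1) / (n_trials - 1)
                speed += rng.normal(0, trial_sd)
                rows.append(
                    (
                        mrow["mouse_id"],
                        mrow["condition"],
                        session,
                        trial,
                        max(speed, 0.0),
                    )
                )
    perf = pd.DataFrame(
        rows, columns=["mouse_id", "condition", "session", "trial", "fall_speed"]
    )
    mouse_truth = pd.DataFrame(
        [
            {
                "mouse_id": m["mouse_id"],
                "condition": m["condition"],
                **{
                    f"wake_iv{k}": m["wake_fractions"][k]
                    for k in range(len(INTERVALS))
                },
                "true_net_nd": m["true_net_nd"],
                "true_session2_onset": m["true_session2_onset"],
            }
            for m in mouse_rows
        ]
    )
    return perf, mouse_truth
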