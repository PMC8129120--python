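"""Spine-level change statistics: ND tables, up/down classification, dendrite
labels, quintile analysis, the max/other partition, proportionality and
ratio-baseline correlations, turnover balance, and behavioral statistics.

Percentages are always computed within mouse first and then averaged across
mice, so each animal contributes equally regardless of how many spines it
carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nd import DOWN, NO_CHANGE, UP, classify_spines, normalized_difference


def nd_table(
    spine_table: pd.DataFrame,
    interval: tuple[str, str] = ("T-24", "T-17"),
    threshold: float = 0.15,
    channel: str = "spine_sep",
) -> pd.DataFrame:
    """Per-spine ND over an ordered timepoint pair, with up/down labels.

    Only spines present at both endpoints are included.  Returns one row per
    spine with columns mouse_id, condition, dendrite_id, spine_id, x_pre,
    x_post, nd, label.
    """
    pre_tp, post_tp = interval
    keys = ["mouse_id", "condition", "dendrite_id", "spine_id"]
    pre = spine_table[
        (spine_table["timepoint"] == pre_tp) & spine_table["present"]
    ].set_index(keys)[channel]
    post = spine_table[
        (spine_table["timepoint"] == post_tp) & spine_table["present"]
    ].set_index(keys)[channel]
    joined = pd.concat(
        [pre.rename("x_pre"), post.rename("x_post")], axis=1, join="inner"
    ).dropna()
    out = joined.reset_index()
    out["nd"] = normalized_difference(out["x_pre"].to_numpy(), out["x_post"].to_numpy())
    out["label"] = classify_spines(out["nd"].to_numpy(), threshold)
    out["interval"] = f"{pre_tp}->{post_tp}"
    out["threshold"] = threshold
    return out


@dataclass
class ClassSummary:
    """Per-mouse up/down percentages and the paired test comparing them."""

    per_mouse: pd.DataFrame  # mouse_id, condition, pct_up, pct_down, pct_no_change, n
    mean_pct_up: float
    sem_pct_up: float
    mean_pct_down: float
    sem_pct_down: float
    t_stat: float
    p_value: float
    n_mice: int


def per_mouse_percentages(nd_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (mouse, cond), grp in nd_df.groupby(["mouse_id", "condition"], sort=True):
        n = len(grp)
        if n == 0:
            raise ValueError(f"mouse {mouse} has no classifiable spines")
        labels = grp["label"].to_numpy()
        rows.append(
            {
                "mouse_id": mouse,
                "condition": cond,
                "pct_up": 100.0 * np.sum(labels == UP) / n,
                "pct_down": 100.0 * np.sum(labels == DOWN) / n,
                "pct_no_change": 100.0 * np.sum(labels == NO_CHANGE) / n,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def _ttest_rel_safe(a, b):
    """Paired t that treats identically-zero differences as no evidence
    (t = 0, p = 1) instead of 0/0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a - b, 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def per_mouse_class_test(nd_df: pd.DataFrame) -> ClassSummary:
    """Two-sided paired t-test across mice on (%up, %down)."""
    per_mouse = per_mouse_percentages(nd_df)
    if len(per_mouse) < 2:
        raise ValueError("paired test requires at least 2 mice")
    up = per_mouse["pct_up"].to_numpy()
    down = per_mouse["pct_down"].to_numpy()
    t_stat, p_value = _ttest_rel_safe(up, down)
    n = len(per_mouse)
    return ClassSummary(
        per_mouse=per_mouse,
        mean_pct_up=float(up.mean()),
        sem_pct_up=float(up.std(ddof=1) / np.sqrt(n)),
        mean_pct_down=float(down.mean()),
        sem_pct_down=float(down.std(ddof=1) / np.sqrt(n)),
        t_stat=t_stat,
        p_value=p_value,
        n_mice=n,
    )


def classify_dendrites(nd_df: pd.DataFrame) -> pd.DataFrame:
    """Label each dendrite up/down/same by strict majority of its up vs down
    spines (ties and equal counts -> same)."""
    rows = []
    for (mouse, dend), grp in nd_df.groupby(["mouse_id", "dendrite_id"], sort=True):
        n_up = int(np.sum(grp["label"].to_numpy() == UP))
        n_down = int(np.sum(grp["label"].to_numpy() == DOWN))
        if n_up > n_down:
            label = UP
        elif n_down > n_up:
            label = DOWN
        else:
            label = "same"
        rows.append(
            {
                "mouse_id": mouse,
                "dendrite_id": dend,
                "n_up": n_up,
                "n_down": n_down,
                "n_spines": len(grp),
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def assign_quintiles(
    spine_table: pd.DataFrame,
    timepoint_pair: tuple[str, str] = ("T-24", "T-17"),
    channel: str = "spine_sep",
) -> pd.DataFrame:
    """Rank spines within each mouse by the mean intensity of two sessions
    and cut into 5 near-equal groups (quintile 1 = weakest).

    Averaging two sessions for the ranking mitigates regression to the mean
    relative to ranking on a single session.  Ties are broken by stable input
    order.  Raises if any mouse has fewer than 5 rankable spines.
    """
    tp_a, tp_b = timepoint_pair
    keys = ["mouse_id", "condition", "dendrite_id", "spine_id"]
    a = spine_table[
        (spine_table["timepoint"] == tp_a) & spine_table["present"]
    ].set_index(keys)[channel]
    b = spine_table[
        (spine_table["timepoint"] == tp_b) & spine_table["present"]
    ].set_index(keys)[channel]
    joined = pd.concat(
        [a.rename("x_a"), b.rename("x_b")], axis=1, join="inner"
    ).dropna()
    joined["rank_stat"] = (joined["x_a"] + joined["x_b"]) / 2.0
    out = joined.reset_index()
    out["quintile"] = 0
    for mouse, grp in out.groupby("mouse_id", sort=False):
        n = len(grp)
        if n < 5:
            raise ValueError(f"mouse {mouse} has fewer than 5 rankable spines")
        order = np.argsort(grp["rank_stat"].to_numpy(), kind="stable")
        quint = np.empty(n, dtype=int)
        for q, chunk in enumerate(np.array_split(np.arange(n), 5), start=1):
            quint[order[chunk]] = q
        out.loc[grp.index, "quintile"] = quint
    return out


def quintile_profile(
    nd_df: pd.DataFrame, quintiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-quintile %up/%down (mouse-averaged) and pooled mean +- SEM of ND.

    ``nd_df`` and ``quintiles`` are joined on spine identity; spines missing
    from either table are dropped.
    """
    keys = ["mouse_id", "spine_id"]
    merged = nd_df.merge(quintiles[keys + ["quintile"]], on=keys, how="inner")
    rows = []
    for q in range(1, 6):
        sub = merged[merged["quintile"] == q]
        per_mouse = []
        for _, grp in sub.groupby("mouse_id"):
            n = len(grp)
            labels = grp["label"].to_numpy()
            per_mouse.append(
                (
                    100.0 * np.sum(labels == UP) / n,
                    100.0 * np.sum(labels == DOWN) / n,
                )
            )
        per_mouse = np.array(per_mouse) if per_mouse else np.zeros((0, 2))
        nd_vals = sub["nd"].to_numpy()
        rows.append(
            {
                "quintile": q,
                "n_spines": len(sub),
                "pct_up": float(per_mouse[:, 0].mean()) if len(per_mouse) else np.nan,
                "pct_down": float(per_mouse[:, 1].mean()) if len(per_mouse) else np.nan,
                "mean_nd": float(nd_vals.mean()) if len(nd_vals) else np.nan,
                "sem_nd": (
                    float(nd_vals.std(ddof=1) / np.sqrt(len(nd_vals)))
                    if len(nd_vals) > 1
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MaxPartition:
    """Spines that underwent the largest learning-associated increase."""

    flags: pd.DataFrame  # spine keys + is_max
    interval: tuple[str, str]
    threshold: float
    n_max: int
    n_total: int
    pct_overall: float
    per_mouse_pct: pd.DataFrame = field(repr=False)


def select_max_spines(
    spine_table: pd.DataFrame,
    interval: tuple[str, str] = ("T-24", "T0"),
    threshold: float = 0.2,
    require_both_baselines: bool = False,
    channel: str = "spine_sep",
) -> MaxPartition:
    """Flag "max" spines: ND > threshold from baseline to post-training.

    With ``require_both_baselines`` the spine must exceed the threshold both
    from the first and from the second pre-training session to the
    post-training session.
    """
    nd1 = nd_table(spine_table, interval, threshold, channel)
    is_max = nd1["nd"].to_numpy() > threshold
    if require_both_baselines:
        alt = ("T-17", interval[1])
        nd2 = nd_table(spine_table, alt, threshold, channel)
        keys = ["mouse_id", "spine_id"]
        merged = nd1[keys].merge(
            nd2[keys + ["nd"]], on=keys, how="left"
        )
        is_max &= merged["nd"].to_numpy() > threshold
    flags = nd1[["mouse_id", "condition", "dendrite_id", "spine_id"]].copy()
    flags["is_max"] = is_max
    per_mouse = (
        flags.groupby("mouse_id")["is_max"].mean().mul(100.0).rename("pct_max")
    ).reset_index()
    n_max = int(is_max.sum())
    n_total = len(flags)
    return MaxPartition(
        flags=flags,
        interval=interval,
        threshold=threshold,
        n_max=n_max,
        n_total=n_total,
        pct_overall=100.0 * n_max / n_total if n_total else np.nan,
        per_mouse_pct=per_mouse,
    )


@dataclass
class ProportionalityResult:
    per_mouse: pd.DataFrame  # mouse_id, value (r or slope)
    method: str
    t_stat: float
    p_value: float
    mean_value: float


def proportionality_test(
    nd_df: pd.DataFrame, method: str = "pearson"
) -> ProportionalityResult:
    """Association between baseline intensity and subsequent change, per
    mouse, with a two-sided one-sample t-test of the per-mouse values vs 0.

    ``method='pearson'`` uses corr(x_pre, x_post - x_pre); ``method='slope'``
    uses the least-squares slope of (x_post - x_pre) on x_pre.
    """
    if method not in ("pearson", "slope"):
        raise ValueError("method must be 'pearson' or 'slope'")
    rows = []
    for mouse, grp in nd_df.groupby("mouse_id", sort=True):
        x = grp["x_pre"].to_numpy()
        delta = grp["x_post"].to_numpy() - x
        if method == "pearson":
            value = float(np.corrcoef(x, delta)[0, 1])
        else:
            value = float(np.polyfit(x, delta, 1)[0])
        rows.append({"mouse_id": mouse, "value": value})
    per_mouse = pd.DataFrame(rows)
    if len(per_mouse) < 2:
        raise ValueError("one-sample t-test requires at least 2 mice")
    res = stats.ttest_1samp(per_mouse["value"].to_numpy(), 0.0)
    return ProportionalityResult(
        per_mouse=per_mouse,
        method=method,
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        mean_value=float(per_mouse["value"].mean()),
    )


def ratio_baseline_correlation(
    x_pre,
    x_post,
    mode: str = "naive",
    measurement_sd: float | None = None,
    seed: int | None = None,
) -> float:
    """Correlation between baseline intensity and the post/pre ratio.

    In ``naive`` mode the same measured baseline enters both variables, so
    measurement noise induces a negative correlation even for completely
    independent observations.  In ``split_half`` mode two pseudo-replicates
    of the baseline with independent noise are constructed by adding and
    subtracting a fresh noise draw of the stated measurement sd; one replicate
    provides the baseline variable and the other the ratio denominator, which
    removes the mechanical coupling.
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if np.any(x_pre <= 0) or np.any(x_post <= 0):
        raise ValueError("intensities must be strictly positive")
    if mode == "naive":
        return float(np.corrcoef(x_pre, x_post / x_pre)[0, 1])
    if mode != "split_half":
        raise ValueError("mode must be 'naive' or 'split_half'")
    if measurement_sd is None:
        raise ValueError("split_half mode requires the measurement noise sd")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, measurement_sd, size=x_pre.shape)
    half_a = x_pre + u
    half_b = x_pre - u
    # a ratio needs a positive denominator; drop the (rare) pairs where the
    # added noise pushes a pseudo-replicate non-positive
    ok = (half_a > 0) & (half_b > 0)
    if ok.sum() < 3:
        raise ValueError("too few valid pairs after split-half noise injection")
    return float(np.corrcoef(half_a[ok], x_post[ok] / half_b[ok])[0, 1])


def turnover_counts(spine_table: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse per-interval formed and eliminated spine counts from the
    presence flags of the long-format table."""
    presence = spine_table.pivot_table(
        index=["mouse_id", "condition", "spine_id"],
        columns="timepoint",
        values="present",
        aggfunc="first",
    )
    tps = [c for c in presence.columns]
    # preserve chronological order as it appears in the table
    order = list(dict.fromkeys(spine_table["timepoint"]))
    tps = [t for t in order if t in tps]
    rows = []
    for (mouse, cond), grp in presence.groupby(["mouse_id", "condition"]):
        mat = grp[tps].fillna(False).to_numpy(dtype=bool)
        for k in range(len(tps) - 1):
            formed = int(np.sum(~mat[:, k] & mat[:, k + 1]))
            eliminated = int(np.sum(mat[:, k] & ~mat[:, k + 1]))
            rows.append(
                {
                    "mouse_id": mouse,
                    "condition": cond,
                    "interval": f"{tps[k]}->{tps[k + 1]}",
                    "formed": formed,
                    "eliminated": eliminated,
                }
            )
    return pd.DataFrame(rows)


def turnover_balance_test(formed, eliminated) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test of per-mouse formed vs eliminated
    counts.  Returns (statistic, two-sided p).  All-zero differences (perfect
    balance in every mouse) give p = 1."""
    formed = np.asarray(formed, dtype=float)
    eliminated = np.asarray(eliminated, dtype=float)
    diffs = formed - eliminated
    if np.all(diffs == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(
        formed, eliminated, zero_method="wilcox", method="exact"
    )
    return float(res.statistic), float(res.pvalue)


def cohens_d(a, b, paired: bool = False) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        d = a - b
        return float(d.mean() / d.std(ddof=1))
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / sp)


@dataclass
class PerformanceStats:
    """Behavioral comparisons for the two-session complex wheel task."""

    session1_within: dict  # paired t: first-3 vs last-3 trial means, all mice
    session2_onset_between: dict  # independent t: S vs SD session-2 first-3
    session1_all_trials_between: dict  # independent t: S vs SD session-1 means


def _trial_means(perf: pd.DataFrame, session: int, trials) -> pd.Series:
    sub = perf[(perf["session"] == session) & perf["trial"].isin(trials)]
    return sub.groupby("mouse_id")["fall_speed"].mean()


def performance_stats(perf: pd.DataFrame) -> PerformanceStats:
    """Within-session-1 learning, session-2 onset group gap, and the overall
    session-1 group comparison, each with t, two-sided p and Cohen's d."""
    n_trials = int(perf["trial"].max())
    first3 = _trial_means(perf, 1, [1, 2, 3])
    last3 = _trial_means(perf, 1, [n_trials - 2, n_trials - 1, n_trials])
    mice = first3.index.intersection(last3.index)
    t1, p1 = _ttest_rel_safe(last3[mice], first3[mice])
    within = {
        "t": t1,
        "p": p1,
        "d": (
            cohens_d(last3[mice], first3[mice], paired=True)
            if not np.allclose(last3[mice], first3[mice])
            else 0.0
        ),
        "n": len(mice),
    }

    cond = perf.groupby("mouse_id")["condition"].first()
    onset2 = _trial_means(perf, 2, [1, 2, 3])
    s_vals = onset2[cond[onset2.index] == "S"].to_numpy()
    sd_vals = onset2[cond[onset2.index] == "SD"].to_numpy()
    res2 = stats.ttest_ind(s_vals, sd_vals)
    between = {
        "t": float(res2.statistic),
        "p": float(res2.pvalue),
        "d": cohens_d(s_vals, sd_vals),
        "mean_S": float(s_vals.mean()),
        "mean_SD": float(sd_vals.mean()),
    }

    all1 = _trial_means(perf, 1, list(range(1, n_trials + 1)))
    s_all = all1[cond[all1.index] == "S"].to_numpy()
    sd_all = all1[cond[all1.index] == "SD"].to_numpy()
    res3 = stats.ttest_ind(s_all, sd_all)
    overall = {
        "t": float(res3.statistic),
        "p": float(res3.pvalue),
        "d": cohens_d(s_all, sd_all),
    }
    return PerformanceStats(
        session1_within=within,
        session2_onset_between=between,
        session1_all_trials_between=overall,
    )


def correlate_performance_nd(nd_per_mouse, speed_per_mouse) -> tuple[float, float]:
    """Pearson r between per-mouse net ND and session-2 onset speed, with a
    two-sided p-value from the Fisher z transform (sd = 1/sqrt(n-3))."""
    nd_per_mouse = np.asarray(nd_per_mouse, dtype=float)
    speed_per_mouse = np.asarray(speed_per_mouse, dtype=float)
    n = len(nd_per_mouse)
    if n < 4 or len(speed_per_mouse) != n:
        raise ValueError("need one (nd, speed) pair per mouse, n >= 4")
    r = float(np.corrcoef(nd_per_mouse, speed_per_mouse)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    z = np.arctanh(r)
    p = 2.0 * stats.norm.sf(abs(z) * np.sqrt(n - 3))
    return r, float(p)
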