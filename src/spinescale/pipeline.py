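"""End-to-end orchestration: simulate -> validate -> ND/classification ->
mixed models -> mechanism fits -> report.

A run is driven by a :class:`RunConfig`; every enabled stage writes its
artifacts under one output directory and contributes to a JSON report whose
tables mirror the study's figure-level summaries (per-interval mean ND,
up/down percentages per threshold, max/other interaction test, the
performance-ND correlation and the mechanism-model comparison).  All
randomness derives from a single root seed, so identical configurations
reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .config import CONDITIONS, INTERVALS, POST_TRAINING_INTERVAL, SynthConfig
from .io import write_performance_table, write_spine_table
from .lme import model1_time_effect, model2_time_condition, model3_max_other, model4_sleep_training
from .mechanism import WakePool, compare_models, fit_model, summarize
from .spine_stats import (
    correlate_performance_nd,
    nd_table,
    per_mouse_class_test,
    performance_stats,
    select_max_spines,
    turnover_balance_test,
    turnover_counts,
)


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    out_dir: str | Path = "spinescale_run"
    nd_thresholds: tuple[float, ...] = (0.1, 0.15, 0.2)
    max_threshold: float = 0.2
    run_stats: bool = True
    run_lme: bool = True
    run_mechfit: bool = True
    mech_n_sim: int | None = None  # defaults to the target sample size


def _stage_seed(root: int, stage: int) -> int:
    ss = np.random.SeedSequence(root)
    return int(ss.spawn(stage + 1)[stage].generate_state(1)[0] % (2**31))


def validate_inputs(spine_table: pd.DataFrame) -> list[dict]:
    """Check SpineTable invariants; returns one record per violation
    (empty list = clean table)."""
    violations = []
    keys = ["mouse_id", "dendrite_id", "spine_id", "timepoint"]
    dup = spine_table.duplicated(subset=keys, keep=False)
    for _, row in spine_table[dup].drop_duplicates(subset=keys).iterrows():
        violations.append(
            {
                "reason": "duplicated (mouse, dendrite, spine, timepoint) key",
                "key": tuple(row[k] for k in keys),
            }
        )
    present = spine_table[spine_table["present"]]
    for col in ("spine_sep", "spine_dsred", "shaft_sep", "shaft_dsred"):
        bad = present[~(present[col] > 0)]
        for _, row in bad.iterrows():
            violations.append(
                {
                    "reason": f"non-positive {col} for a present spine",
                    "key": tuple(row[k] for k in keys),
                }
            )
    n_tp = spine_table["timepoint"].nunique()
    rows_per_spine = spine_table.groupby("spine_id")["timepoint"].nunique()
    for spine in rows_per_spine[rows_per_spine != n_tp].index:
        violations.append(
            {"reason": "spine lacks a row at every timepoint", "key": (spine,)}
        )
    for child, parent in [("spine_id", "dendrite_id"), ("dendrite_id", "mouse_id")]:
        parents = spine_table.groupby(child)[parent].nunique()
        for key in parents[parents > 1].index:
            violations.append(
                {"reason": f"{child} maps to multiple {parent} values", "key": (key,)}
            )
    return violations


def _interval_nd_summary(spine_table: pd.DataFrame) -> list[dict]:
    """Mean +- SEM ND per interval; the first two intervals precede the
    S/SD split and are pooled, the later ones are split by condition."""
    rows = []
    for k, (a, b) in enumerate(INTERVALS):
        if k < POST_TRAINING_INTERVAL:
            groups = [("all", nd_table(spine_table, (a, b)))]
        else:
            groups = [
                (cond, nd_table(spine_table[spine_table["condition"] == cond], (a, b)))
                for cond in CONDITIONS
            ]
        for name, nd in groups:
            vals = nd["nd"].to_numpy()
            rows.append(
                {
                    "interval": f"{a}->{b}",
                    "group": name,
                    "mean_nd": float(vals.mean()),
                    "sem_nd": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                    "n_spines": int(len(vals)),
                }
            )
    return rows


def _classification_summary(spine_table: pd.DataFrame, thresholds) -> list[dict]:
    rows = []
    intervals = {
        "pre_learning_sleep": (("T-24", "T-17"), None),
        "learning": (("T-24", "T0"), None),
        "post_learning_sleep": (("T0", "T7"), "S"),
        "post_learning_sd": (("T0", "T7"), "SD"),
    }
    for name, (interval, cond) in intervals.items():
        table = spine_table if cond is None else spine_table[
            spine_table["condition"] == cond
        ]
        for thr in thresholds:
            nd = nd_table(table, interval, threshold=thr)
            summ = per_mouse_class_test(nd)
            rows.append(
                {
                    "analysis": name,
                    "interval": f"{interval[0]}->{interval[1]}",
                    "threshold": thr,
                    "mean_pct_up": summ.mean_pct_up,
                    "mean_pct_down": summ.mean_pct_down,
                    "paired_t": summ.t_stat,
                    "p_value": summ.p_value,
                    "n_mice": summ.n_mice,
                }
            )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write report + artifacts.

    Returns the report dict (also written as ``report.json`` with a
    human-readable ``report.txt`` beside it).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(config.synth.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        },
        "stages": [],
    }

    spine_table, perf, truth = generate_cohort(config.synth, seed=_stage_seed(config.seed, 0))
    write_spine_table(spine_table, out / "spine_table.csv")
    write_performance_table(perf, out / "performance.csv")
    truth.spines.to_csv(out / "ground_truth_spines.csv", index=False)
    truth.mice.to_csv(out / "ground_truth_mice.csv", index=False)
    report["stages"].append("simulate")

    violations = validate_inputs(spine_table)
    report["validation"] = {"n_violations": len(violations)}
    if violations:
        report["validation"]["violations"] = violations[:50]

    if not config.run_stats:
        report["note"] = "downstream stages skipped"
        _write_report(report, out)
        return report

    report["interval_nd"] = _interval_nd_summary(spine_table)
    report["classification"] = _classification_summary(
        spine_table, config.nd_thresholds
    )

    counts = turnover_counts(spine_table)
    balance = []
    for interval, grp in counts.groupby("interval", sort=False):
        stat, p = turnover_balance_test(
            grp["formed"].to_numpy(), grp["eliminated"].to_numpy()
        )
        balance.append(
            {
                "interval": interval,
                "formed_total": int(grp["formed"].sum()),
                "eliminated_total": int(grp["eliminated"].sum()),
                "wilcoxon_p": p,
            }
        )
    report["turnover_balance"] = balance

    partition = select_max_spines(spine_table, threshold=config.max_threshold)
    report["max_spines"] = {
        "n_max": partition.n_max,
        "n_total": partition.n_total,
        "pct_overall": partition.pct_overall,
        "threshold": partition.threshold,
    }

    perf_stats = performance_stats(perf)
    nd_post = nd_table(spine_table, ("T0", "T7"))
    nd_per_mouse = nd_post.groupby("mouse_id")["nd"].mean()
    onset = perf[(perf["session"] == 2) & (perf["trial"] <= 3)].groupby(
        "mouse_id"
    )["fall_speed"].mean()
    mice = nd_per_mouse.index.intersection(onset.index)
    r, p = correlate_performance_nd(nd_per_mouse[mice], onset[mice])
    report["performance"] = {
        "session1_within": perf_stats.session1_within,
        "session2_onset_between": perf_stats.session2_onset_between,
        "nd_correlation": {"r": r, "p": p, "n_mice": int(len(mice))},
    }
    report["stages"].append("stats")

    if config.run_lme:
        m1 = model1_time_effect(spine_table)
        m2 = model2_time_condition(spine_table)
        m3 = model3_max_other(spine_table, partition)
        m4 = model4_sleep_training(spine_table)
        report["lme"] = {
            "model1_time": m1.to_dict(),
            "model2_time_condition": m2.to_dict(),
            "model3_max_other": m3.to_dict(),
            "model4_sleep_training": m4.to_dict(),
        }
        report["stages"].append("lme")

    if config.run_mechfit:
        nd_sleep = nd_table(spine_table, ("T-24", "T-17"))
        pre = nd_sleep["x_pre"].to_numpy()
        post = nd_sleep["x_post"].to_numpy()
        target = summarize(pre, post)
        sd_nd = nd_table(spine_table[spine_table["condition"] == "SD"], ("T0", "T7"))
        pool = WakePool.from_intensities(
            sd_nd["x_pre"].to_numpy(), sd_nd["x_post"].to_numpy()
        )
        n_sim = config.mech_n_sim or len(pre)
        moments = (float(pre.mean()), float(pre.var(ddof=1)))
        fit_pot = fit_model(
            "potentiation", target, moments,
            seed=_stage_seed(config.seed, 1), n_sim=n_sim,
        )
        fit_wake = fit_model(
            "intervening_wake", target, moments, pool=pool,
            seed=_stage_seed(config.seed, 2), n_sim=n_sim,
        )
        report["mechanism"] = compare_models(fit_pot, fit_wake)
        report["stages"].append("mechfit")

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
    lines = ["spinescale run report", "=" * 60]
    lines.append(f"seed: {report['provenance']['seed']}")
    lines.append(f"stages: {', '.join(report['stages'])}")
    if "interval_nd" in report:
        lines.append("\nMean ND per interval (mean +- SEM):")
        for row in report["interval_nd"]:
            lines.append(
                f"  {row['interval']:>12} [{row['group']:>3}]  "
                f"{row['mean_nd']:+.4f} +- {row['sem_nd']:.4f}  (n={row['n_spines']})"
            )
    if "classification" in report:
        lines.append("\nUp/down percentages (per mouse, paired t):")
        for row in report["classification"]:
            lines.append(
                f"  {row['analysis']:>20} thr={row['threshold']:.2f}  "
                f"up {row['mean_pct_up']:5.1f}%  down {row['mean_pct_down']:5.1f}%  "
                f"p={row['p_value']:.4f}"
            )
    if "max_spines" in report:
        m = report["max_spines"]
        lines.append(
            f"\nMax spines: {m['n_max']}/{m['n_total']} = {m['pct_overall']:.1f}% "
            f"(ND > {m['threshold']})"
        )
    if "performance" in report:
        c = report["performance"]["nd_correlation"]
        lines.append(
            f"Performance vs net ND: r = {c['r']:+.3f}, p = {c['p']:.4f} "
            f"(n = {c['n_mice']} mice)"
        )
    if "lme" in report:
        lines.append("\nMixed-model LRTs:")
        for name, res in report["lme"].items():
            lines.append(
                f"  {name:>24}: chi2 = {res['lrt']['statistic']:.2f} "
                f"(df {res['lrt']['df']}), p = {res['lrt']['p_value']:.3g}"
            )
    if "mechanism" in report:
        mech = report["mechanism"]
        lines.append("\nMechanism-model comparison:")
        for name, m in mech["models"].items():
            lines.append(
                f"  {name:>18}: core error {m['core_error']:.3f}, "
                f"quintile error {m['quintile_error']:.3f}"
            )
        lines.append(f"  quintile-criterion winner: {mech['winner_quintile_error']}")
    with open(out / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
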