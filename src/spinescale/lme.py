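"""Nested linear mixed-effect models for longitudinal spine intensities.

Four model structures are provided as thin wrappers over maximum-likelihood
Gaussian mixed models with nested random intercepts (spine within dendrite
within mouse, or dendrite within mouse):

1. time (3 pre/post-training levels) on sqrt-intensity, all mice;
2. time x condition (S vs SD) on sqrt-intensity over the post-training
   interval;
3. condition x learning (max vs other spines) on the raw 7h-0h intensity
   difference, optionally extended with a time factor (7h-0h vs 24h-0h);
4. sleep x training factorial recoding of the four main sessions,
   S-condition spines only, on sqrt-intensity.

Intensity models use a square-root response transform to stabilise variance.
Fixed effects are tested with likelihood-ratio tests; effect size is
Cohen's f^2 computed from marginal R^2 (variance of the fixed-effect
predictor over total modelled variance).  Post-hoc pairwise contrasts are
corrected either by the multivariate-normal max-|z| simultaneous method or
by Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .spine_stats import nd_table, select_max_spines

__all__ = [
    "LMEFit",
    "LRTResult",
    "fit_lme",
    "lrt",
    "posthoc",
    "model1_time_effect",
    "model2_time_condition",
    "model3_max_other",
    "model4_sleep_training",
]


@dataclass
class LMEFit:
    formula: str
    llf: float
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    n_fixed: int
    variance_components: dict
    resid_var: float
    marginal_r2: float
    converged: bool
    n_obs: int
    result: object = field(repr=False, default=None)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    cohens_f2: float


def fit_lme(
    data: pd.DataFrame,
    formula: str,
    groups: str = "mouse_id",
    vc_levels: tuple[str, ...] = ("dendrite_id", "spine_id"),
) -> LMEFit:
    """ML fit of a Gaussian mixed model with a random intercept per group
    and one variance component per nesting level in ``vc_levels``.

    Identifiers must be unique across the table (nesting is then implied).
    Non-convergence is reported on the returned fit, never silently.
    """
    vc = {lvl: f"0 + C({lvl})" for lvl in vc_levels}
    model = smf.mixedlm(formula, data, groups=groups, re_formula="1", vc_formula=vc)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                candidate = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result is None or candidate.converged:
                result = candidate
            if candidate.converged:
                break
    if result is None:
        raise RuntimeError(f"mixed-model fit failed for: {formula}")
    fe = result.fe_params
    exog = result.model.exog
    fitted_fixed = exog @ fe.to_numpy()
    var_fixed = float(np.var(fitted_fixed))
    var_group = float(np.asarray(result.cov_re).ravel()[0])
    vcomp = {name: float(v) for name, v in zip(vc, result.vcomp)}
    total = var_fixed + var_group + sum(vcomp.values()) + float(result.scale)
    return LMEFit(
        formula=formula,
        llf=float(result.llf),
        fe_params=fe,
        cov_fe=result.cov_params().loc[fe.index, fe.index],
        n_fixed=len(fe),
        variance_components={groups: var_group, **vcomp},
        resid_var=float(result.scale),
        marginal_r2=var_fixed / total if total > 0 else np.nan,
        converged=bool(result.converged),
        n_obs=int(result.nobs),
        result=result,
    )


def lrt(full: LMEFit, reduced: LMEFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits: statistic 2*(l_full - l_red),
    chi-square df = difference in fixed-effect count, plus Cohen's f^2 from
    the marginal R^2 of the two fits."""
    if not (full.converged and reduced.converged):
        raise RuntimeError("likelihood-ratio test requires converged fits")
    df = full.n_fixed - reduced.n_fixed
    if df <= 0:
        raise ValueError("reduced model must have fewer fixed parameters")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    p = float(stats.chi2.sf(stat, df))
    r2f, r2r = full.marginal_r2, reduced.marginal_r2
    f2 = (r2f - r2r) / (1.0 - r2f) if r2f < 1 else np.inf
    return LRTResult(statistic=float(stat), df=df, p_value=p, cohens_f2=float(f2))


def posthoc(
    fit: LMEFit, contrasts: dict[str, np.ndarray], method: str = "mvn"
) -> pd.DataFrame:
    """Simultaneous tests of fixed-effect contrasts.

    ``contrasts`` maps a name to a coefficient vector over the fixed
    effects.  ``method='mvn'`` adjusts each p as 1 - P(max_j |Z_j| <= |z_k|)
    under the joint normal of the contrast z-statistics (single-step
    correction); ``method='bonferroni'`` multiplies by the number of
    contrasts.  A single contrast is returned unadjusted.
    """
    names = list(contrasts)
    C = np.vstack([np.asarray(contrasts[k], dtype=float) for k in names])
    beta = fit.fe_params.to_numpy()
    V = fit.cov_fe.to_numpy()
    est = C @ beta
    cov = C @ V @ C.T
    se = np.sqrt(np.diag(cov))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    k = len(names)
    if k == 1:
        p_adj = p_raw.copy()
    elif method == "bonferroni":
        p_adj = np.minimum(k * p_raw, 1.0)
    elif method == "mvn":
        R = cov / np.outer(se, se)
        if not np.all(np.isfinite(R)):
            # degenerate contrast covariance (e.g. a barely-identified fit):
            # fall back to the conservative Bonferroni bound
            p_adj = np.minimum(k * p_raw, 1.0)
        else:
            mvn = stats.multivariate_normal(
                mean=np.zeros(k), cov=R, allow_singular=True
            )
            p_adj = np.empty(k)
            for i, zi in enumerate(z):
                c = abs(zi)
                inside = mvn.cdf(np.full(k, c), lower_limit=np.full(k, -c))
                p_adj[i] = min(max(1.0 - float(inside), p_raw[i]), 1.0)
    else:
        raise ValueError("method must be 'mvn' or 'bonferroni'")
    return pd.DataFrame(
        {
            "contrast": names,
            "estimate": est,
            "se": se,
            "z": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )


def _pairwise_level_contrasts(fit: LMEFit, factor: str) -> dict[str, np.ndarray]:
    """All pairwise contrasts between the levels of a treatment-coded
    categorical fixed factor (no interactions present)."""
    idx = list(fit.fe_params.index)
    level_cols = {"<ref>": None}
    for i, name in enumerate(idx):
        if name.startswith(f"C({factor})[T.") and name.endswith("]"):
            level_cols[name.split("[T.")[1][:-1]] = i
    levels = list(level_cols)
    out = {}
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            c = np.zeros(len(idx))
            if level_cols[levels[b]] is not None:
                c[level_cols[levels[b]]] = 1.0
            if level_cols[levels[a]] is not None:
                c[level_cols[levels[a]]] = -1.0
            out[f"{levels[b]} - {levels[a]}"] = c
    return out


def _sqrt_response(
    spine_table: pd.DataFrame, timepoints, channel: str = "spine_sep"
) -> pd.DataFrame:
    sub = spine_table[
        spine_table["timepoint"].isin(timepoints) & spine_table["present"]
    ].dropna(subset=[channel])
    # only spines observed at every requested session enter the model
    counts = sub.groupby("spine_id")["timepoint"].nunique()
    keep = counts[counts == len(timepoints)].index
    sub = sub[sub["spine_id"].isin(keep)].copy()
    sub["y"] = np.sqrt(sub[channel])
    # chronological factor order (the first session is the reference level)
    sub["timepoint"] = pd.Categorical(
        sub["timepoint"], categories=list(timepoints), ordered=True
    )
    return sub


@dataclass
class ModelResult:
    full: LMEFit
    reduced: LMEFit
    lrt: LRTResult
    posthoc: pd.DataFrame | None
    data_rows: int

    def to_dict(self) -> dict:
        d = {
            "formula": self.full.formula,
            "n_obs": self.full.n_obs,
            "fixed_effects": self.full.fe_params.to_dict(),
            "variance_components": self.full.variance_components,
            "resid_var": self.full.resid_var,
            "lrt": {
                "statistic": self.lrt.statistic,
                "df": self.lrt.df,
                "p_value": self.lrt.p_value,
                "cohens_f2": self.lrt.cohens_f2,
            },
            "converged": self.full.converged and self.reduced.converged,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def model1_time_effect(
    spine_table: pd.DataFrame,
    timepoints=("T-24", "T-17", "T0"),
    posthoc_method: str = "mvn",
) -> ModelResult:
    """Effect of time (pre-sleep, post-sleep, post-training) on
    sqrt-intensity with spine/dendrite/mouse random intercepts."""
    data = _sqrt_response(spine_table, timepoints)
    full = fit_lme(data, "y ~ C(timepoint)")
    reduced = fit_lme(data, "y ~ 1")
    test = lrt(full, reduced)
    ph = posthoc(full, _pairwise_level_contrasts(full, "timepoint"), posthoc_method)
    return ModelResult(full, reduced, test, ph, len(data))


def model2_time_condition(
    spine_table: pd.DataFrame, timepoints=("T0", "T7"), posthoc_method: str = "mvn"
) -> ModelResult:
    """Time x condition (S vs SD) interaction over the post-training
    interval; post-hoc within-condition time contrasts."""
    data = _sqrt_response(spine_table, timepoints)
    full = fit_lme(data, "y ~ C(timepoint) * C(condition)")
    reduced = fit_lme(data, "y ~ C(timepoint) + C(condition)")
    test = lrt(full, reduced)
    idx = list(full.fe_params.index)
    tp_b = [n for n in idx if n.startswith("C(timepoint)[T.") and ":" not in n]
    inter = [n for n in idx if ":" in n]
    c_s = np.zeros(len(idx))
    c_s[idx.index(tp_b[0])] = 1.0
    c_sd = c_s.copy()
    c_sd[idx.index(inter[0])] = 1.0
    ph = posthoc(
        full,
        {"time effect | S": c_s, "time effect | SD": c_sd},
        posthoc_method,
    )
    return ModelResult(full, reduced, test, ph, len(data))


def model3_max_other(
    spine_table: pd.DataFrame,
    partition=None,
    time_extension: bool = False,
    threshold: float = 0.2,
) -> ModelResult:
    """Condition x learning (max vs other) on the raw post-interval intensity
    change, with dendrite and mouse random intercepts only.

    The response is the intensity difference 7h-0h; with ``time_extension``
    both 7h-0h and 24h-0h differences enter, with time and its interaction
    with learning added, and the reported LRT is on time x learning.
    """
    if partition is None:
        partition = select_max_spines(spine_table, threshold=threshold)
    flags = partition.flags.set_index("spine_id")["is_max"]

    def diffs(post_tp):
        nd = nd_table(spine_table, ("T0", post_tp))
        nd = nd[nd["spine_id"].isin(flags.index)].copy()
        nd["delta"] = nd["x_post"] - nd["x_pre"]
        nd["learning"] = np.where(
            flags[nd["spine_id"]].to_numpy(), "max", "other"
        )
        nd["time"] = post_tp
        return nd[
            ["mouse_id", "condition", "dendrite_id", "spine_id", "delta",
             "learning", "time"]
        ]

    if not time_extension:
        data = diffs("T7")
        full = fit_lme(
            data, "delta ~ C(condition) * C(learning)", vc_levels=("dendrite_id",)
        )
        reduced = fit_lme(
            data, "delta ~ C(condition) + C(learning)", vc_levels=("dendrite_id",)
        )
    else:
        data = pd.concat([diffs("T7"), diffs("T24")], ignore_index=True)
        full = fit_lme(
            data,
            "delta ~ C(condition) * C(learning) + C(time) * C(learning)",
            vc_levels=("dendrite_id",),
        )
        reduced = fit_lme(
            data,
            "delta ~ C(condition) * C(learning) + C(time) + C(learning)",
            vc_levels=("dendrite_id",),
        )
    test = lrt(full, reduced)
    return ModelResult(full, reduced, test, None, len(data))


def model4_sleep_training(spine_table: pd.DataFrame) -> ModelResult:
    """Sleep x training factorial over the four main sessions, S mice only,
    with dendrite and mouse random intercepts.

    Sessions recode as sleep: before (T-24, T0) / after (T-17, T7) and
    training: before (T-24, T-17) / after (T0, T7); the LRT is on the
    sleep x training interaction.
    """
    s_table = spine_table[spine_table["condition"] == "S"]
    data = _sqrt_response(s_table, ("T-24", "T-17", "T0", "T7"))
    sleep_map = {"T-24": "before", "T0": "before", "T-17": "after", "T7": "after"}
    train_map = {"T-24": "before", "T-17": "before", "T0": "after", "T7": "after"}
    data = data.copy()
    data["sleep"] = data["timepoint"].map(sleep_map)
    data["training"] = data["timepoint"].map(train_map)
    full = fit_lme(
        data, "y ~ C(sleep) * C(training)", vc_levels=("dendrite_id",)
    )
    reduced = fit_lme(
        data, "y ~ C(sleep) + C(training)", vc_levels=("dendrite_id",)
    )
    test = lrt(full, reduced)
    return ModelResult(full, reduced, test, None, len(data))
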