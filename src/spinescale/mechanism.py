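"""Generative models of the sleep-interval change in spine intensities and
their relative-error fitting.

Two competing mechanisms for the pre-sleep -> post-sleep intensity change
are implemented:

* **Sleep-dependent potentiation** (5 parameters): a fraction ``p_up`` of
  spines is multiplicatively upscaled by ``m_up`` and a disjoint fraction
  ``p_down`` downscaled by ``m_down`` during sleep, plus additive
  independent Gaussian noise of sd ``sigma_ind``.
* **Intervening-wake potentiation** (4 parameters): sleep only downscales
  (``p_down``, ``m_down``); apparent upscaling arises from a size-dependent
  wake-noise component bootstrapped from the observed pure-wake changes of
  sleep-deprived animals, matched by baseline quintile and scaled so the
  wake component's overall standard deviation is ``sigma_wake``; additive
  independent noise ``sigma_ind`` is shared with the first model.

Both models start from a log-normal baseline sample whose natural-scale
mean and variance match the data.  A fitted model is scored by the summed
absolute relative error of its simulated summary statistics (post mean and
variance, pre/post correlation, up/down proportions at ND threshold 0.15,
optionally the per-quintile up/down proportions) against the target sample.
Candidate evaluations reuse common random numbers, making the objective a
deterministic function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cohort import lognormal_params

ND_THRESHOLD_DEFAULT = 0.15
CORE_STATS = ("mean_post", "var_post", "corr_pre_post", "prop_up", "prop_down")
_FLOOR_FRAC = 1e-6


@dataclass
class PotentiationParams:
    """Sleep-dependent potentiation model (5 free parameters)."""

    p_up: float
    m_up: float
    p_down: float
    m_down: float
    sigma_ind: float

    def validate(self) -> None:
        if not (0 <= self.p_up <= 1 and 0 <= self.p_down <= 1):
            raise ValueError("proportions must lie in [0, 1]")
        if self.p_up + self.p_down > 1 + 1e-12:
            raise ValueError("p_up + p_down must not exceed 1")
        if self.p_up > 0 and self.m_up <= 1:
            raise ValueError("m_up must be > 1")
        if self.p_down > 0 and not 0 < self.m_down < 1:
            raise ValueError("m_down must lie in (0, 1)")
        if self.sigma_ind < 0:
            raise ValueError("sigma_ind must be >= 0")


@dataclass
class WakeNoiseParams:
    """Intervening-wake potentiation model (4 free parameters)."""

    p_down: float
    m_down: float
    sigma_ind: float
    sigma_wake: float

    def validate(self) -> None:
        if not 0 <= self.p_down <= 1:
            raise ValueError("p_down must lie in [0, 1]")
        if self.p_down > 0 and not 0 < self.m_down < 1:
            raise ValueError("m_down must lie in (0, 1)")
        if self.sigma_ind < 0 or self.sigma_wake < 0:
            raise ValueError("noise scales must be >= 0")


def quintile_labels(values: np.ndarray) -> np.ndarray:
    """0-based quintile label per element, by rank with near-equal sizes
    (stable ties; quintile 0 = smallest)."""
    values = np.asarray(values)
    n = len(values)
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    for q, chunk in enumerate(np.array_split(np.arange(n), 5)):
        labels[order[chunk]] = q
    return labels


@dataclass
class WakePool:
    """Per-quintile pools of observed pre -> post intensity changes from the
    pure-wake condition, indexed by baseline quintile."""

    deltas: list  # 5 arrays
    quintile_sds: np.ndarray = field(init=False)
    pooled_sd: float = field(init=False)

    def __post_init__(self):
        if len(self.deltas) != 5 or any(len(d) == 0 for d in self.deltas):
            raise ValueError("wake pool requires 5 non-empty quintile pools")
        self.deltas = [np.asarray(d, dtype=float) for d in self.deltas]
        self.quintile_sds = np.array([d.std() for d in self.deltas])
        self.pooled_sd = float(np.concatenate(self.deltas).std())

    @classmethod
    def from_intensities(cls, pre, post) -> "WakePool":
        """Build the pool from paired pure-wake intensities, quintiles cut
        on the pre-intensity ranking of this sample."""
        pre = np.asarray(pre, dtype=float)
        post = np.asarray(post, dtype=float)
        labels = quintile_labels(pre)
        return cls(deltas=[post[labels == q] - pre[labels == q] for q in range(5)])


def simulate_baseline(
    n: int, target_mean: float, target_var: float, seed=None
) -> np.ndarray:
    """n log-normal draws whose distribution parameters solve the
    natural-scale moment equations for (target_mean, target_var)."""
    mu, sigma = lognormal_params(target_mean, target_var)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, size=n)


@dataclass
class _Draws:
    """Common random numbers shared across candidate evaluations."""

    u_event: np.ndarray  # uniforms assigning up/down events
    z_ind: np.ndarray  # standard normals for independent noise
    u_pool: np.ndarray  # uniforms indexing bootstrap pool entries

    @classmethod
    def generate(cls, n: int, rng: np.random.Generator) -> "_Draws":
        return cls(
            u_event=rng.random(n),
            z_ind=rng.standard_normal(n),
            u_pool=rng.random(n),
        )


def _floor(values: np.ndarray, pre: np.ndarray) -> np.ndarray:
    return np.maximum(values, _FLOOR_FRAC * float(np.mean(pre)))


def apply_sleep_potentiation(
    pre: np.ndarray,
    params: PotentiationParams,
    seed=None,
    draws: _Draws | None = None,
) -> np.ndarray:
    """Apply the 5-parameter up/down-scaling mechanism to a baseline sample.

    A fraction ``p_down`` of spines (lowest event uniforms) is multiplied by
    ``m_down``, a disjoint fraction ``p_up`` (highest uniforms) by ``m_up``;
    independent Gaussian noise is added to every spine and the result is
    floored at a small positive value.
    """
    params.validate()
    pre = np.asarray(pre, dtype=float)
    if draws is None:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        draws = _Draws.generate(len(pre), rng)
    factor = np.ones(len(pre))
    factor[draws.u_event < params.p_down] = params.m_down
    factor[draws.u_event > 1.0 - params.p_up] = params.m_up
    post = pre * factor + params.sigma_ind * draws.z_ind
    return _floor(post, pre)


def apply_intervening_wake(
    pre: np.ndarray,
    params: WakeNoiseParams,
    pool: WakePool,
    seed=None,
    draws: _Draws | None = None,
    rescale: str = "global",
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the 4-parameter downscale-plus-wake-noise mechanism.

    Each spine is matched to the wake pool quintile of its baseline rank
    (this sample's own quintile cut points) and receives a bootstrap-sampled
    wake change from that pool.  With ``rescale='global'`` (default) every
    pool delta is scaled by one factor so the wake component's overall sd is
    ``sigma_wake`` while preserving the relative quintile spreads (the size
    dependence); ``rescale='per_quintile'`` scales each quintile pool to sd
    ``sigma_wake``; ``rescale='raw'`` uses the pool deltas unscaled and
    ignores ``sigma_wake``.
    """
    params.validate()
    pre = np.asarray(pre, dtype=float)
    if draws is None:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        draws = _Draws.generate(len(pre), rng)
    factor = np.ones(len(pre))
    factor[draws.u_event < params.p_down] = params.m_down
    post = pre * factor + params.sigma_ind * draws.z_ind

    if labels is None:
        labels = quintile_labels(pre)
    wake = np.empty(len(pre))
    for q in range(5):
        mask = labels == q
        pool_q = pool.deltas[q]
        idx = np.minimum(
            (draws.u_pool[mask] * len(pool_q)).astype(int), len(pool_q) - 1
        )
        wake[mask] = pool_q[idx]
    if rescale == "global":
        if params.sigma_wake == 0:
            wake = np.zeros_like(wake)
        elif pool.pooled_sd == 0:
            raise ValueError("degenerate pool: cannot rescale to sigma_wake > 0")
        else:
            wake *= params.sigma_wake / pool.pooled_sd
    elif rescale == "per_quintile":
        if params.sigma_wake == 0:
            wake = np.zeros_like(wake)
        else:
            if np.any(pool.quintile_sds == 0):
                raise ValueError("degenerate quintile pool: cannot rescale")
            scale = params.sigma_wake / pool.quintile_sds
            wake *= scale[labels]
    elif rescale != "raw":
        raise ValueError("rescale must be 'global', 'per_quintile' or 'raw'")
    return _floor(post + wake, pre)


@dataclass
class SummaryStats:
    """Matched statistics of a pre -> post intensity pair."""

    mean_post: float
    var_post: float
    corr_pre_post: float
    prop_up: float
    prop_down: float
    quintile_prop_up: np.ndarray  # (5,)
    quintile_prop_down: np.ndarray  # (5,)
    n: int
    nd_threshold: float = ND_THRESHOLD_DEFAULT

    def as_dict(self) -> dict:
        d = {k: float(getattr(self, k)) for k in CORE_STATS}
        for q in range(5):
            d[f"q{q + 1}_prop_up"] = float(self.quintile_prop_up[q])
            d[f"q{q + 1}_prop_down"] = float(self.quintile_prop_down[q])
        return d


def summarize(
    pre,
    post,
    nd_threshold: float = ND_THRESHOLD_DEFAULT,
    labels: np.ndarray | None = None,
) -> SummaryStats:
    """Compute all matched statistics; per-quintile proportions use quintiles
    of the pre-intensity ranking (precomputed labels may be passed when the
    same baseline is summarised repeatedly)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length vectors")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise ValueError("intensities must be strictly positive")
    nd = (post - pre) / (post + pre)
    up = nd > nd_threshold
    down = nd < -nd_threshold
    if labels is None:
        labels = quintile_labels(pre)
    counts = np.bincount(labels, minlength=5)
    q_up = np.bincount(labels, weights=up, minlength=5) / counts
    q_down = np.bincount(labels, weights=down, minlength=5) / counts
    return SummaryStats(
        mean_post=float(post.mean()),
        var_post=float(post.var(ddof=1)),
        corr_pre_post=float(np.corrcoef(pre, post)[0, 1]),
        prop_up=float(up.mean()),
        prop_down=float(down.mean()),
        quintile_prop_up=q_up,
        quintile_prop_down=q_down,
        n=len(pre),
        nd_threshold=nd_threshold,
    )


def total_relative_error(
    simulated: SummaryStats,
    target: SummaryStats,
    stat_set: str = "core",
    signed: bool = False,
) -> tuple[float, dict]:
    """Aggregate relative errors (true - estimated)/true of the simulated
    statistics against the target.

    ``stat_set='core'`` uses mean, variance, correlation and the two overall
    proportions; ``'core+quintile'`` adds the 10 per-quintile proportions;
    ``'quintile'`` uses only those 10.  The default aggregation is the sum
    of absolute relative errors; ``signed=True`` sums them with sign (for
    diagnostics only — signed errors can cancel).
    """
    sim = simulated.as_dict()
    tgt = target.as_dict()
    if stat_set == "core":
        keys = list(CORE_STATS)
    elif stat_set == "core+quintile":
        keys = list(sim)
    elif stat_set == "quintile":
        keys = [k for k in sim if k.startswith("q")]
    else:
        raise ValueError("stat_set must be 'core', 'core+quintile' or 'quintile'")
    breakdown = {}
    for k in keys:
        if tgt[k] == 0:
            raise ValueError(f"target statistic {k} is 0: relative error undefined")
        breakdown[k] = (tgt[k] - sim[k]) / tgt[k]
    if signed:
        total = float(sum(breakdown.values()))
    else:
        total = float(sum(abs(v) for v in breakdown.values()))
    return total, breakdown


def simulate_dataset(
    model: str,
    params,
    n: int,
    pre_moments: tuple[float, float],
    pool: WakePool | None = None,
    seed: int = 0,
    rescale: str = "global",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one (pre, post) dataset from a mechanism model.

    Uses exactly the random-number layout of :func:`fit_model`'s candidate
    evaluations, so a fit run with the same ``seed`` and ``n`` evaluates its
    candidates on the very draws that generated the data: the objective is
    exactly zero at the generating parameters (the common-random-numbers
    protocol used for in-silico recovery experiments).
    """
    rng = np.random.default_rng(seed)
    pre = simulate_baseline(n, pre_moments[0], pre_moments[1], rng)
    draws = _Draws.generate(n, rng)
    if model == "potentiation":
        post = apply_sleep_potentiation(pre, params, draws=draws)
    elif model in ("intervening_wake", "wake"):
        if pool is None:
            raise ValueError("intervening-wake model requires a wake pool")
        post = apply_intervening_wake(pre, params, pool, draws=draws, rescale=rescale)
    else:
        raise ValueError("model must be 'potentiation' or 'intervening_wake'")
    return pre, post


@dataclass
class FitResult:
    model: str
    params: dict
    total_error: float
    breakdown: dict
    stat_set: str
    seed: int
    n_sim: int
    n_evaluations: int
    fitted_summary: SummaryStats
    target: SummaryStats
    success: bool
    rescale: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "total_error": self.total_error,
            "breakdown": self.breakdown,
            "stat_set": self.stat_set,
            "seed": self.seed,
            "n_sim": self.n_sim,
            "n_evaluations": self.n_evaluations,
            "success": self.success,
            "fitted_summary": self.fitted_summary.as_dict(),
            "target_summary": self.target.as_dict(),
        }


_POT_GRID = {
    "p_up": (0.02, 0.1, 0.25, 0.45),
    "m_up": (1.15, 1.4, 1.8, 2.4),
    "p_down": (0.02, 0.1, 0.25, 0.45),
    "m_down": (0.45, 0.6, 0.75, 0.9),
    "sigma_ind": (0.02, 0.08, 0.2, 0.4),
}
_WAKE_GRID = {
    "p_down": (0.02, 0.1, 0.25, 0.45),
    "m_down": (0.45, 0.6, 0.75, 0.9),
    "sigma_ind": (0.02, 0.08, 0.2, 0.4),
    "sigma_wake": (0.02, 0.08, 0.2, 0.4),
}
_POT_BOUNDS = {
    "p_up": (0.0, 0.6),
    "m_up": (1.001, 4.0),
    "p_down": (0.0, 0.6),
    "m_down": (0.2, 0.999),
    "sigma_ind": (0.0, 1.5),
}
_WAKE_BOUNDS = {
    "p_down": (0.0, 0.6),
    "m_down": (0.2, 0.999),
    "sigma_ind": (0.0, 1.5),
    "sigma_wake": (0.0, 1.5),
}


def fit_model(
    model: str,
    target: SummaryStats,
    pre_moments: tuple[float, float],
    pool: WakePool | None = None,
    seed: int = 0,
    n_sim: int = 1530,
    stat_set: str = "core+quintile",
    rescale: str = "global",
    nelder_mead_maxiter: int = 400,
    de_budget: tuple[int, int, int] = (2, 60, 18),
) -> FitResult:
    """Fit one mechanism model to target statistics by deterministic coarse
    grid search plus Nelder-Mead refinement under common random numbers.

    ``pre_moments`` is the (mean, variance) of the observed pre-sleep
    intensities; noise scales are searched relative to sqrt(variance).
    """
    if model == "potentiation":
        grid, bounds = _POT_GRID, _POT_BOUNDS
    elif model in ("intervening_wake", "wake"):
        model = "intervening_wake"
        if pool is None:
            raise ValueError("intervening-wake model requires a wake pool")
        grid, bounds = _WAKE_GRID, _WAKE_BOUNDS
    else:
        raise ValueError("model must be 'potentiation' or 'intervening_wake'")

    rng = np.random.default_rng(seed)
    pre = simulate_baseline(n_sim, pre_moments[0], pre_moments[1], rng)
    draws = _Draws.generate(n_sim, rng)
    labels = quintile_labels(pre)
    sd_scale = float(np.sqrt(pre_moments[1]))
    names = list(grid)
    n_evals = 0

    def evaluate(vec):
        nonlocal n_evals
        kw = dict(zip(names, vec))
        for k, (lo, hi) in bounds.items():
            if not lo <= kw[k] <= hi:
                return np.inf, None, None
        try:
            if model == "potentiation":
                if kw["p_up"] + kw["p_down"] > 1:
                    return np.inf, None, None
                params = PotentiationParams(**kw)
                post = apply_sleep_potentiation(pre, params, draws=draws)
            else:
                params = WakeNoiseParams(**kw)
                post = apply_intervening_wake(
                    pre, params, pool, draws=draws, rescale=rescale, labels=labels
                )
            n_evals += 1
            summary = summarize(pre, post, target.nd_threshold, labels=labels)
            err, brk = total_relative_error(summary, target, stat_set)
            return err, summary, brk
        except ValueError:
            return np.inf, None, None

    # coarse grid: noise scales are relative to the target sd
    axes = []
    for k in names:
        vals = np.asarray(grid[k], dtype=float)
        if k.startswith("sigma"):
            vals = vals * sd_scale
        axes.append(vals)
    mesh = np.meshgrid(*axes, indexing="ij")
    candidates = np.column_stack([m.ravel() for m in mesh])
    grid_errs = np.array([evaluate(vec)[0] for vec in candidates])
    if not np.any(np.isfinite(grid_errs)):
        raise RuntimeError("no grid candidate achieved a finite objective")
    order = np.argsort(grid_errs)
    best_vec = candidates[order[0]].copy()
    best_err = float(grid_errs[order[0]])

    # global refinement: the objective is rugged (bootstrap/event steps of
    # size 1/n), so a population-based search precedes local polish
    de_bounds = []
    for k in names:
        lo, hi = bounds[k]
        if k.startswith("sigma"):
            hi = min(hi, 1.0 * sd_scale)
        de_bounds.append((lo, hi))
    n_runs, de_maxiter, de_popsize = de_budget
    for run in range(n_runs):
        de = optimize.differential_evolution(
            lambda v: evaluate(v)[0],
            de_bounds,
            seed=(seed + run * 1_000_003) % (2**31),
            maxiter=de_maxiter,
            popsize=de_popsize,
            tol=1e-8,
            init="sobol",
            polish=False,
        )
        if np.isfinite(de.fun) and de.fun < best_err:
            best_err = float(de.fun)
            best_vec = de.x.copy()

    # local polish: repeated Nelder-Mead from the best candidates found
    starts = [best_vec, best_vec, candidates[order[0]]]
    for start in starts:
        res = optimize.minimize(
            lambda v: evaluate(v)[0],
            start,
            method="Nelder-Mead",
            options={
                "maxiter": nelder_mead_maxiter,
                "xatol": 1e-5,
                "fatol": 1e-6,
            },
        )
        if np.isfinite(res.fun) and res.fun < best_err:
            best_err = float(res.fun)
            best_vec = res.x.copy()
        starts[1] = best_vec
    final_vec = best_vec
    err, summary, brk = evaluate(final_vec)
    return FitResult(
        model=model,
        params=dict(zip(names, (float(v) for v in final_vec))),
        total_error=float(err),
        breakdown={k: float(v) for k, v in brk.items()},
        stat_set=stat_set,
        seed=seed,
        n_sim=n_sim,
        n_evaluations=n_evals,
        fitted_summary=summary,
        target=target,
        success=bool(np.isfinite(err)),
        rescale=rescale if model == "intervening_wake" else None,
    )


def compare_models(fit_pot: FitResult, fit_wake: FitResult) -> dict:
    """Side-by-side comparison of the two fitted mechanisms.

    Reports each model's core and quintile-level summed absolute relative
    errors against its target, the per-quintile predicted vs target up/down
    proportions, and the winner under each criterion ('tie' on equality).
    """
    report = {"models": {}}
    for fit in (fit_pot, fit_wake):
        core_err, _ = total_relative_error(fit.fitted_summary, fit.target, "core")
        quint_err, _ = total_relative_error(
            fit.fitted_summary, fit.target, "quintile"
        )
        report["models"][fit.model] = {
            "params": fit.params,
            "core_error": core_err,
            "quintile_error": quint_err,
            "total_error": fit.total_error,
            "per_quintile": {
                "predicted_up": fit.fitted_summary.quintile_prop_up.tolist(),
                "target_up": fit.target.quintile_prop_up.tolist(),
                "predicted_down": fit.fitted_summary.quintile_prop_down.tolist(),
                "target_down": fit.target.quintile_prop_down.tolist(),
            },
        }
    for crit in ("core_error", "quintile_error"):
        a = report["models"][fit_pot.model][crit]
        b = report["models"][fit_wake.model][crit]
        if a == b:
            report[f"winner_{crit}"] = "tie"
        else:
            report[f"winner_{crit}"] = (
                fit_pot.model if a < b else fit_wake.model
            )
    return report
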