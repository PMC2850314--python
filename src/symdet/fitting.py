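"""Threshold estimation and model fitting.

Psychometric thresholds are estimated per (condition, masker density)
block by maximum-likelihood Weibull fits to yes/no percent correct.  The
channel model is fitted to a TvD dataset by least squares on log10
thresholds over its nine free parameters, with the cued/high-salience
excitatory sensitivity anchored at 1000.  A nested F comparison tests the
full model against the uncertainty-only reduction in which cueing may not
change the excitatory sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    CONDITIONS,
    CUED,
    HIGH,
    LOW,
    NONCUED,
    ChannelParams,
    Condition,
    DecisionConfig,
    TvDDataset,
    thresholds,
)

__all__ = [
    "dprime_to_pc",
    "PsychometricFit",
    "fit_psychometric",
    "thresholds_from_trials",
    "FitConfig",
    "FitResult",
    "fit_model",
    "goodness_of_fit",
    "nested_f",
    "compare_nested",
    "slope_report",
    "ANCHOR_S_ET",
]

ANCHOR_S_ET = 1000.0

TRIAL_COLUMNS = (
    "condition_cue", "condition_salience", "masker_density",
    "target_density", "axis_deg", "stimulus_class", "response", "correct",
)


def dprime_to_pc(dprime: float, mapping: str = "yesno") -> float:
    """Percent correct corresponding to a d' value.

    "yesno": unbiased yes/no criterion, P = Phi(d'/2) (default).
    "2afc": two-interval convention, P = Phi(d'/sqrt(2)).
    """
    if mapping == "yesno":
        return float(stats.norm.cdf(dprime / 2.0))
    if mapping == "2afc":
        return float(stats.norm.cdf(dprime / np.sqrt(2.0)))
    raise ValueError(f"unknown mapping {mapping!r}")


class PsychometricFitError(RuntimeError):
    """Degenerate data or non-convergence in a psychometric fit."""


@dataclass
class PsychometricFit:
    """Weibull fit of percent correct vs target density for one block."""

    alpha: float
    beta: float
    guess: float
    lapse: float
    threshold: float
    threshold_se: float
    n_trials: int
    pc_threshold: float


def _weibull_pc(d, alpha, beta, guess, lapse):
    d = np.asarray(d, dtype=float)
    return guess + (1.0 - guess - lapse) * (1.0 - np.exp(-((d / alpha) ** beta)))


def _weibull_threshold(alpha, beta, guess, lapse, pc_target):
    frac = (pc_target - guess) / (1.0 - guess - lapse)
    if not (0.0 < frac < 1.0):
        raise PsychometricFitError(
            f"target percent correct {pc_target} outside the fitted range"
        )
    return float(alpha * (-np.log1p(-frac)) ** (1.0 / beta))


def _fit_weibull_mle(levels, n_correct, n_trials, guess, lapse):
    levels = np.asarray(levels, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)

    def nll(x):
        alpha = 10.0 ** np.clip(x[0], -8.0, 2.0)
        beta = np.exp(np.clip(x[1], np.log(0.05), np.log(50.0)))
        p = np.clip(_weibull_pc(levels, alpha, beta, guess, lapse), 1e-9, 1 - 1e-9)
        return -np.sum(n_correct * np.log(p) + (n_trials - n_correct) * np.log1p(-p))

    pc = n_correct / n_trials
    # start near the level closest to the psychometric midpoint
    mid = guess + (1.0 - guess - lapse) / 2.0
    a0 = levels[np.argmin(np.abs(pc - mid))]
    best = None
    for b0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        res = optimize.minimize(
            nll, x0=[np.log10(a0), np.log(b0)], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha = float(10.0 ** np.clip(best.x[0], -8.0, 2.0))
    beta = float(np.exp(np.clip(best.x[1], np.log(0.05), np.log(50.0))))
    return alpha, beta


def fit_psychometric(target_density, n_correct, n_trials,
                     dprime_criterion: float = 1.0, pc_mapping: str = "yesno",
                     guess: float = 0.5, lapse: float = 0.01,
                     n_boot: int = 200, seed=None) -> PsychometricFit:
    """ML Weibull fit of one block's percent-correct data.

    Threshold is read off at the percent-correct level corresponding to
    ``dprime_criterion`` under ``pc_mapping``; its standard error comes
    from a parametric bootstrap (``n_boot`` refits; 0 skips it).
    Requires at least 4 density levels with at least 10 trials each;
    all-correct or all-wrong data raise :class:`PsychometricFitError`.
    """
    levels = np.asarray(target_density, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    if levels.size < 4:
        raise ValueError("need >= 4 target-density levels")
    if np.any(n_trials < 10):
        raise ValueError("need >= 10 trials per level")
    if not (0.0 <= lapse <= 0.03):
        raise ValueError("lapse must lie in [0, 0.03]")
    if np.all(n_correct == n_trials) or np.all(n_correct == 0):
        raise PsychometricFitError("degenerate data: all correct or all wrong")

    alpha, beta = _fit_weibull_mle(levels, n_correct, n_trials, guess, lapse)
    pc_thr = dprime_to_pc(dprime_criterion, pc_mapping)
    thr = _weibull_threshold(alpha, beta, guess, lapse, pc_thr)

    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        p_fit = _weibull_pc(levels, alpha, beta, guess, lapse)
        boot = []
        for _ in range(n_boot):
            k = rng.binomial(n_trials.astype(int), p_fit)
            if np.all(k == n_trials) or np.all(k == 0):
                continue
            a_b, b_b = _fit_weibull_mle(levels, k, n_trials, guess, lapse)
            try:
                boot.append(_weibull_threshold(a_b, b_b, guess, lapse, pc_thr))
            except PsychometricFitError:
                continue
        if len(boot) >= 10:
            se = float(np.std(np.log10(boot), ddof=1) * np.log(10) * thr)
    return PsychometricFit(alpha, beta, guess, lapse, thr, se,
                           int(n_trials.sum()), pc_thr)


def thresholds_from_trials(trials: pd.DataFrame, dprime_criterion: float = 1.0,
                           pc_mapping: str = "yesno", lapse: float = 0.01,
                           n_boot: int = 200, seed=None,
                           min_levels: int = 4) -> TvDDataset:
    """Psychometric thresholds for every (condition, masker density)
    block of a trial table, assembled into a TvD dataset."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns) - {"axis_deg"}
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    keys = ["condition_cue", "condition_salience", "masker_density"]
    for (cue, sal, db), block in trials.groupby(keys, sort=True):
        agg = block.groupby("target_density")["correct"].agg(["sum", "count"])
        if len(agg) < min_levels:
            continue
        fit = fit_psychometric(
            agg.index.to_numpy(), agg["sum"].to_numpy(), agg["count"].to_numpy(),
            dprime_criterion=dprime_criterion, pc_mapping=pc_mapping,
            lapse=lapse, n_boot=n_boot, seed=rng.integers(2**32),
        )
        # Weibull thresholds can extrapolate past the physical density
        # ceiling on ill-behaved blocks; clamp to the valid range
        rows.append((Condition(cue, sal), float(db),
                     min(fit.threshold, 1.0), fit.threshold_se))
    if not rows:
        raise ValueError("no block had enough levels to fit")
    return TvDDataset.from_rows(rows)


# ---------------------------------------------------------------------------
# model fitting

# free-parameter order for the full (9) and reduced (7) models
_FULL_NAMES = ("s_et_cued_low", "s_et_noncued_high", "s_et_noncued_low",
               "s_eb", "s_it_high", "s_it_low", "s_ib", "z_prime", "p")
_REDUCED_NAMES = ("s_et_low", "s_eb", "s_it_high", "s_it_low", "s_ib",
                  "z_prime", "p")

_SENS_BOUNDS = (-6.0, 5.0)      # log10 of [1e-6, 1e5]
_Z_BOUNDS = (-4.0, 4.0)         # log10 of [1e-4, 1e4]
_P_BOUNDS = (np.log10(1.0), np.log10(5.0))


@dataclass
class FitConfig:
    """Settings for :func:`fit_model`."""

    n_starts: int = 20
    seed: int = 0
    reduced: bool = False
    dprime_criterion: float = 1.0
    maxiter: int = 600
    compute_hessian: bool = False
    grouping: str = "separate"

    def free_names(self) -> tuple[str, ...]:
        return _REDUCED_NAMES if self.reduced else _FULL_NAMES


def _bounds_for(config: FitConfig) -> list[tuple[float, float]]:
    out = []
    for name in config.free_names():
        if name == "p":
            out.append(_P_BOUNDS)
        elif name == "z_prime":
            out.append(_Z_BOUNDS)
        else:
            out.append(_SENS_BOUNDS)
    return out


def _vector_to_params(x: np.ndarray, config: FitConfig) -> ChannelParams:
    v = 10.0 ** np.asarray(x, dtype=float)
    if config.reduced:
        et_l, eb, it_h, it_l, ib, z, p = v
        s_et = {(CUED, HIGH): ANCHOR_S_ET, (CUED, LOW): et_l,
                (NONCUED, HIGH): ANCHOR_S_ET, (NONCUED, LOW): et_l}
    else:
        et_cl, et_nh, et_nl, eb, it_h, it_l, ib, z, p = v
        s_et = {(CUED, HIGH): ANCHOR_S_ET, (CUED, LOW): et_cl,
                (NONCUED, HIGH): et_nh, (NONCUED, LOW): et_nl}
    return ChannelParams(s_et=s_et, s_eb=eb, s_it={HIGH: it_h, LOW: it_l},
                         s_ib=ib, z_prime=z, p=p, grouping=config.grouping)


_FAIL_RESIDUAL = 3.0  # log10 units charged per unreachable threshold

# coarser solver settings during the search (resolution ~2e-9 log units,
# far below data precision but fast); finite-difference steps must stay
# well above this quantization
_FIT_SOLVER = {"n_scan": 41, "n_bisect": 26}
_DIFF_STEP = 1e-3


def _model_log_thresholds(params: ChannelParams, groups) -> np.ndarray:
    out = []
    for cond, decision, d_b in groups:
        thr = thresholds(d_b, params, cond, decision, on_fail="nan",
                         **_FIT_SOLVER)
        out.append(np.log10(thr))
    return np.concatenate(out)


@dataclass
class FitResult:
    """Best-fitting parameters plus goodness-of-fit diagnostics."""

    params: ChannelParams
    sse_log: float
    rmse_log: float
    variance_explained: float
    n_points: int
    n_free_params: int
    free_values: dict
    residuals: pd.DataFrame
    seed: int
    n_starts: int
    reduced: bool
    hessian_condition_number: float | None = None
    identifiability_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "free_parameters": self.free_values,
            "anchor_s_et_cued_high": ANCHOR_S_ET,
            "fixed": {"q": self.params.q, "anchor": ANCHOR_S_ET},
            "sse_log": self.sse_log,
            "rmse_log": self.rmse_log,
            "variance_explained": self.variance_explained,
            "n_points": self.n_points,
            "n_free_params": self.n_free_params,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "reduced": self.reduced,
            "hessian_condition_number": self.hessian_condition_number,
            "identifiability_warning": self.identifiability_warning,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _initial_points(config: FitConfig, rng: np.random.Generator) -> np.ndarray:
    """One magnitude-informed start plus random starts in the log box."""
    bounds = np.array(_bounds_for(config))
    heur = {"s_et_cued_low": 2.6, "s_et_noncued_high": 2.7,
            "s_et_noncued_low": 2.4, "s_et_low": 2.5, "s_eb": 1.0,
            "s_it_high": 2.7, "s_it_low": 2.4, "s_ib": 3.3,
            "z_prime": 0.0, "p": np.log10(2.3)}
    x0 = np.array([heur[name] for name in config.free_names()])
    n_random = max(config.n_starts - 1, 0)
    lo = np.maximum(bounds[:, 0], x0 - 2.0)
    hi = np.minimum(bounds[:, 1], x0 + 2.0)
    rand = rng.uniform(lo, hi, size=(n_random, len(x0)))
    return np.vstack([x0[None, :], rand])[: config.n_starts]


def fit_model(tvd: TvDDataset, config: FitConfig | None = None) -> FitResult:
    """Least-squares fit of the channel model to a TvD dataset.

    Minimizes the sum of squared log10-threshold errors over the free
    parameters (9 full / 7 reduced) in log-parameter space, multi-start
    bounded least squares with a fixed seed.  Unreachable thresholds
    during the search are penalized, not fatal.
    """
    if config is None:
        config = FitConfig()
    names = config.free_names()
    if len(tvd) <= len(names):
        raise ValueError(
            f"need more data points ({len(tvd)}) than free parameters ({len(names)})"
        )
    conds = tvd.conditions()
    if len(conds) < 2:
        raise ValueError("need data from at least 2 conditions")

    groups = []
    y_parts = []
    res_rows = []
    for cond in conds:
        sub = tvd.subset(cond).table
        d_b = sub["masker_density"].to_numpy()
        decision = DecisionConfig.for_condition(cond, config.dprime_criterion)
        groups.append((cond, decision, d_b))
        y_parts.append(np.log10(sub["threshold_density"].to_numpy()))
        res_rows.append(sub[["condition_cue", "condition_salience",
                             "masker_density", "threshold_density"]])
    y_log = np.concatenate(y_parts)

    def residual_vec(x):
        try:
            params = _vector_to_params(x, config)
        except ValueError:
            return np.full(y_log.size, _FAIL_RESIDUAL)
        r = _model_log_thresholds(params, groups) - y_log
        return np.where(np.isfinite(r), r, _FAIL_RESIDUAL)

    def objective(x):
        return float(np.sum(residual_vec(x) ** 2))

    rng = np.random.default_rng(config.seed)
    bounds = np.array(_bounds_for(config))
    best_x, best_sse = None, np.inf
    for x0 in _initial_points(config, rng):
        res = optimize.least_squares(
            residual_vec, x0, bounds=(bounds[:, 0], bounds[:, 1]),
            method="trf", diff_step=_DIFF_STEP, xtol=1e-12, ftol=1e-12,
            gtol=1e-12, max_nfev=config.maxiter,
        )
        sse = 2.0 * res.cost
        if sse < best_sse:
            best_x, best_sse = res.x, sse

    params = _vector_to_params(best_x, config)
    pred = _model_log_thresholds(params, groups)
    resid = pred - y_log
    resid = np.where(np.isfinite(resid), resid, _FAIL_RESIDUAL)
    sse = float(np.sum(resid**2))
    n = y_log.size
    rmse = float(np.sqrt(sse / n))
    sst = float(np.sum((y_log - y_log.mean()) ** 2))
    varexp = 1.0 - sse / sst if sst > 0 else float("nan")

    residuals = pd.concat(res_rows, ignore_index=True)
    residuals["log10_observed"] = y_log
    residuals["log10_predicted"] = pred
    residuals["residual_log10"] = resid

    hess_cond = None
    warn = False
    if config.compute_hessian:
        hess_cond = _hessian_condition(objective, best_x)
        warn = not np.isfinite(hess_cond) or hess_cond > 1e8

    free_values = {name: float(10.0 ** xv) for name, xv in zip(names, best_x)}
    return FitResult(
        params=params, sse_log=sse, rmse_log=rmse, variance_explained=varexp,
        n_points=n, n_free_params=len(names), free_values=free_values,
        residuals=residuals, seed=config.seed, n_starts=config.n_starts,
        reduced=config.reduced, hessian_condition_number=hess_cond,
        identifiability_warning=warn,
    )


def _hessian_condition(fun, x, h: float = 1e-3) -> float:
    """Condition number of a central finite-difference Hessian."""
    x = np.asarray(x, dtype=float)
    k = x.size
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                val = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h**2
            else:
                val = (fun(x + ei + ej) - fun(x + ei - ej)
                       - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h**2)
            hess[i, j] = hess[j, i] = val
    sv = np.linalg.svd(hess, compute_uv=False)
    if sv[-1] <= 0:
        return float("inf")
    return float(sv[0] / sv[-1])


def goodness_of_fit(fit: FitResult) -> dict:
    """Fit-quality report: global RMSE / variance explained plus
    per-condition residual summaries."""
    per_cond = (
        fit.residuals.groupby(["condition_cue", "condition_salience"])
        ["residual_log10"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_residual_log10",
                         "std": "sd_residual_log10", "count": "n_points"})
    )
    return {
        "rmse_log": fit.rmse_log,
        "variance_explained": fit.variance_explained,
        "n_points": fit.n_points,
        "n_free_params": fit.n_free_params,
        "per_condition": per_cond,
    }


@dataclass(frozen=True)
class NestedComparison:
    f_stat: float
    df1: int
    df2: int
    p_value: float


def nested_f(sse_reduced: float, sse_full: float, n_points: int,
             n_free_full: int, n_free_reduced: int) -> NestedComparison:
    """Textbook nested-model F test on sums of squared errors."""
    ddf = n_free_full - n_free_reduced
    df2 = n_points - n_free_full
    if ddf <= 0 or df2 <= 0:
        raise ValueError("invalid degrees of freedom for the nested comparison")
    if sse_full <= 0:
        raise ZeroDivisionError("full-model SSE is zero; F is degenerate")
    f = ((sse_reduced - sse_full) / ddf) / (sse_full / df2)
    p = float(stats.f.sf(f, ddf, df2))
    return NestedComparison(float(f), ddf, df2, p)


def compare_nested(full: FitResult, reduced: FitResult) -> NestedComparison:
    """F comparison of the full model against the uncertainty-only
    reduction (S_et shared across cue conditions; 2 fewer parameters)."""
    if full.n_points != reduced.n_points:
        raise ValueError("fits must use the same data")
    return nested_f(reduced.sse_log, full.sse_log, full.n_points,
                    full.n_free_params, reduced.n_free_params)


def slope_report(tvd: TvDDataset, density_range: tuple[float, float] | None = None,
                 min_points: int = 3) -> pd.DataFrame:
    """Per-condition log-log TvD slopes plus salience means and the
    overall mean (arithmetic mean of condition slopes)."""
    from .model import tvd_slope

    rows = []
    for cond in tvd.conditions():
        sub = tvd.subset(cond)
        t = sub.table
        sel = t["masker_density"] > 0
        if density_range is not None:
            lo, hi = density_range
            sel &= (t["masker_density"] >= lo) & (t["masker_density"] <= hi)
        if sel.sum() < min_points:
            raise ValueError(
                f"condition {cond.label}: fewer than {min_points} points in range"
            )
        rows.append({"condition_cue": cond.cue,
                     "condition_salience": cond.salience,
                     "slope": tvd_slope(sub, density_range)})
    out = pd.DataFrame(rows)
    summary = [
        {"condition_cue": "mean", "condition_salience": sal,
         "slope": out.loc[out["condition_salience"] == sal, "slope"].mean()}
        for sal in sorted(out["condition_salience"].unique())
    ]
    summary.append({"condition_cue": "mean", "condition_salience": "all",
                    "slope": out["slope"].mean()})
    return pd.concat([out, pd.DataFrame(summary)], ignore_index=True)
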