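"""Model-driven synthetic datasets with the experiment's structure.

Generates constant-stimulus designs (2x2 conditions, masker densities
from 0 to 10%, 7-9 target levels in 0.15-log steps straddling the model
threshold), simulates a max-rule observer trial by trial, and builds
parameter-recovery suites for the fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import mean_max_shifted
from .model import (
    CONDITIONS,
    ChannelParams,
    Condition,
    DecisionConfig,
    NoThresholdError,
    TvDDataset,
    channel_response,
    control_response,
    pooled_response,
    thresholds,
    threshold,
)

__all__ = [
    "DEFAULT_MASKER_DENSITIES",
    "Block",
    "ExperimentDesign",
    "generate_design",
    "simulate_observer",
    "pooling_approximation_report",
    "RecoveryReport",
    "make_recovery_suite",
]

LOG_STEP = 0.15

# 0 (unmasked) plus log-spaced coverage of -3.5 .. -1 log units (10%)
DEFAULT_MASKER_DENSITIES: tuple[float, ...] = (
    0.0, 10**-3.5, 10**-3.0, 10**-2.5, 10**-2.0, 10**-1.5, 10**-1.0,
)


@dataclass
class Block:
    """One constant-stimulus block: a condition x masker-density cell."""

    condition: Condition
    masker_density: float
    target_levels: np.ndarray
    trials_per_level: int

    def to_dict(self) -> dict:
        return {
            "condition_cue": self.condition.cue,
            "condition_salience": self.condition.salience,
            "masker_density": self.masker_density,
            "target_levels": [float(v) for v in self.target_levels],
            "trials_per_level": self.trials_per_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Block":
        return cls(
            Condition(d["condition_cue"], d["condition_salience"]),
            float(d["masker_density"]),
            np.asarray(d["target_levels"], dtype=float),
            int(d["trials_per_level"]),
        )


@dataclass
class ExperimentDesign:
    """Full constant-stimulus design plus bookkeeping."""

    blocks: list[Block]
    seed: int
    skipped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "blocks": [b.to_dict() for b in self.blocks],
            "skipped": self.skipped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls([Block.from_dict(b) for b in d["blocks"]], int(d["seed"]),
                   list(d.get("skipped", [])))

    def conditions(self) -> list[Condition]:
        seen = []
        for b in self.blocks:
            if b.condition not in seen:
                seen.append(b.condition)
        return seen


def _level_grid(center: float, n_levels: int) -> np.ndarray:
    """n_levels target densities in LOG_STEP steps centered on ``center``."""
    offsets = (np.arange(n_levels) - (n_levels - 1) / 2.0) * LOG_STEP
    return np.minimum(center * 10.0**offsets, 1.0)


def generate_design(params: ChannelParams, trials_per_level: int = 100,
                    seed: int = 0, masker_densities=DEFAULT_MASKER_DENSITIES,
                    conditions=CONDITIONS, n_levels: int | None = None,
                    dprime_criterion: float = 1.0) -> ExperimentDesign:
    """Design whose target grids straddle the generating model's threshold.

    Each (condition, masker density) cell gets 7-9 levels (drawn
    per cell unless ``n_levels`` pins it) in 0.15-log steps centered on
    the model threshold.  Cells with no reachable threshold are flagged
    in ``design.skipped`` rather than raising.
    """
    rng = np.random.default_rng(seed)
    blocks: list[Block] = []
    skipped: list[dict] = []
    for cond in conditions:
        decision = DecisionConfig.for_condition(cond, dprime_criterion)
        for db in masker_densities:
            try:
                thr = threshold(float(db), params, cond, decision)
            except NoThresholdError:
                skipped.append({"condition_cue": cond.cue,
                                "condition_salience": cond.salience,
                                "masker_density": float(db),
                                "reason": "threshold unreachable"})
                continue
            levels = int(rng.integers(7, 10)) if n_levels is None else n_levels
            blocks.append(Block(cond, float(db), _level_grid(thr, levels),
                                trials_per_level))
    return ExperimentDesign(blocks, seed, skipped)


def _block_means(block: Block, params: ChannelParams,
                 decision: DecisionConfig):
    """Per-level mean responses of responding/mismatched channels for the
    target stimulus, and of all channels for the control stimulus."""
    dt = block.target_levels
    db = block.masker_density
    r_target = np.atleast_1d(channel_response(dt, db, params, block.condition))
    r_control = np.atleast_1d(control_response(dt, db, params, block.condition))
    return r_target, r_control


def simulate_observer(design: ExperimentDesign, params: ChannelParams,
                      seed: int = 0, lapse: float = 0.0,
                      dprime_criterion: float = 1.0,
                      rule: str = "max") -> pd.DataFrame:
    """Trial-level yes/no simulation of the model observer.

    ``rule="max"`` (default) draws the m monitored channels as unit-SD
    Gaussians around their model mean responses (the responding channel
    sees the symmetric component on target trials; mismatched channels
    respond as to a random image of the same total density) and takes
    their maximum, so the fourth-power pooling approximation error of
    the decision stage is itself measurable (see
    :func:`pooling_approximation_report`).  ``rule="pooled"`` draws the
    decision variable from the model's own Gaussian abstraction of the
    max (mean = fourth-power pooled response, SD = gamma), which
    reproduces the d'-to-percent-correct mapping exactly; the two rules
    coincide for the cued conditions (m = 1).

    The observer responds "target" iff the decision variable exceeds an
    unbiased criterion placed midway between the two classes' expected
    decision-variable values at the trial's target level.
    """
    if rule not in ("max", "pooled"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for block in design.blocks:
        decision = DecisionConfig.for_condition(block.condition, dprime_criterion)
        m, n = decision.m, decision.n
        r_target, r_control = _block_means(block, params, decision)
        for lev, rt, rc in zip(block.target_levels, r_target, r_control):
            nt = block.trials_per_level
            is_target = rng.random(nt) < 0.5
            axes = rng.choice([0, 45, 90, 135], size=nt)
            if rule == "max":
                # criterion midway between the TRUE expected maxima (the
                # fourth-power pooled mean lacks the order-statistic
                # offset of the max of m noisy channels)
                crit = rc + 0.5 * (mean_max_shifted(rt - rc, m)
                                   + mean_max_shifted(0.0, m))
                means = np.where(
                    is_target[:, None],
                    np.concatenate([[rt] * n, [rc] * (m - n)])[None, :],
                    np.full(m, rc)[None, :],
                )
                dv = (means + rng.standard_normal((nt, m))).max(axis=1)
            else:
                pooled_t = pooled_response(rt, rc, m, n)
                pooled_c = pooled_response(rc, rc, m, n)
                crit = 0.5 * (pooled_t + pooled_c)
                means = np.where(is_target, pooled_t, pooled_c)
                dv = means + decision.gamma * rng.standard_normal(nt)
            say_target = dv > crit
            if lapse > 0:
                lapsed = rng.random(nt) < lapse
                say_target = np.where(lapsed, rng.random(nt) < 0.5, say_target)
            for i in range(nt):
                cls = "target" if is_target[i] else "control"
                ans = "target" if say_target[i] else "control"
                rows.append((block.condition.cue, block.condition.salience,
                             block.masker_density, float(lev), int(axes[i]),
                             cls, ans, cls == ans))
    return pd.DataFrame(rows, columns=[
        "condition_cue", "condition_salience", "masker_density",
        "target_density", "axis_deg", "stimulus_class", "response", "correct",
    ])


def pooling_approximation_report(params: ChannelParams, condition: Condition,
                                 d_t: float, d_b: float,
                                 decision: DecisionConfig | None = None,
                                 n_samples: int = 200_000,
                                 seed: int = 0) -> dict:
    """Fourth-power pooled mean vs the empirical mean of the max.

    The trial simulation uses the true max rule, so the pooling
    approximation error of the decision stage is directly measurable.
    """
    if decision is None:
        decision = DecisionConfig.for_condition(condition)
    rng = np.random.default_rng(seed)
    m, n = decision.m, decision.n
    rt = float(channel_response(d_t, d_b, params, condition))
    rc = float(control_response(d_t, d_b, params, condition))
    means = np.concatenate([[rt] * n, [rc] * (m - n)])
    samples = means[None, :] + rng.standard_normal((n_samples, m))
    emp = float(samples.max(axis=1).mean())
    approx = pooled_response(rt, rc, m, n)
    return {"pooled_fourth_power": approx, "empirical_mean_max": emp,
            "difference": approx - emp, "m": m, "n": n,
            "n_samples": n_samples}


@dataclass
class RecoveryReport:
    """Outcome of a parameter-recovery suite."""

    replicates: pd.DataFrame   # rmse_log, variance_explained, recovery_rmse_log
    noise_sd_log: float
    seed: int

    def summary(self) -> dict:
        r = self.replicates
        return {
            "n_replicates": len(r),
            "median_rmse_log": float(r["rmse_log"].median()),
            "median_variance_explained": float(r["variance_explained"].median()),
            "median_recovery_rmse_log": float(r["recovery_rmse_log"].median()),
            "noise_sd_log": self.noise_sd_log,
            "seed": self.seed,
        }


def make_recovery_suite(true_params: ChannelParams, noise_sd_log: float = 0.08,
                        n_replicates: int = 5, seed: int = 0,
                        masker_densities=DEFAULT_MASKER_DENSITIES,
                        conditions=CONDITIONS, fit_config=None
                        ) -> tuple[list[TvDDataset], RecoveryReport]:
    """Fit replicated noisy copies of the model's own threshold surface.

    Model thresholds on the (condition, masker density) grid are
    perturbed by Gaussian log10-threshold noise of SD ``noise_sd_log``
    and refitted; the report collects per-replicate fit RMSE, variance
    explained, and the recovery error of the fitted threshold surface
    against the generating one.
    """
    from .fitting import FitConfig, fit_model

    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be >= 0")
    rng = np.random.default_rng(seed)
    truth = []
    for cond in conditions:
        decision = DecisionConfig.for_condition(cond)
        d_b = np.asarray(masker_densities, dtype=float)
        thr = thresholds(d_b, true_params, cond, decision)
        truth.append((cond, decision, d_b, np.log10(thr)))

    datasets: list[TvDDataset] = []
    recs = []
    for rep in range(n_replicates):
        rows = []
        for cond, _, d_b, log_thr in truth:
            noisy = log_thr + noise_sd_log * rng.standard_normal(log_thr.size)
            for db, lt in zip(d_b, noisy):
                rows.append((cond, float(db), float(np.minimum(10.0**lt, 1.0)),
                             noise_sd_log))
        tvd = TvDDataset.from_rows(rows)
        datasets.append(tvd)

        cfg = fit_config if fit_config is not None else FitConfig()
        cfg = FitConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
        fit = fit_model(tvd, cfg)
        rec_sq = []
        for cond, decision, d_b, log_thr in truth:
            fitted = thresholds(d_b, fit.params, cond, decision, on_fail="nan")
            rec_sq.append((np.log10(fitted) - log_thr) ** 2)
        rec_rmse = float(np.sqrt(np.nanmean(np.concatenate(rec_sq))))
        recs.append({"replicate": rep, "rmse_log": fit.rmse_log,
                     "variance_explained": fit.variance_explained,
                     "recovery_rmse_log": rec_rmse})
    report = RecoveryReport(pd.DataFrame(recs), noise_sd_log, seed)
    return datasets, report
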