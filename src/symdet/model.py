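"""Channel model of symmetry detection under noise masking.

The perception stage maps the dot densities of the stimulus components
(symmetric target, random masker) onto a channel response through a
power-law excitation divided by a gain-control denominator.  The decision
stage pools the monitored channels with a fourth-power summation that
approximates the mean of the max rule, and converts the target/control
response difference into d'.  Detection threshold is the smallest target
density at which d' reaches the criterion (1 by default).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CUED",
    "NONCUED",
    "HIGH",
    "LOW",
    "Condition",
    "CONDITIONS",
    "ChannelParams",
    "DecisionConfig",
    "TvDDataset",
    "NoThresholdError",
    "ModelDomainError",
    "TABLE1_PARAMS",
    "DOUBLE_CORNER_PARAMS",
    "excitation",
    "channel_response",
    "control_response",
    "pooled_response",
    "dprime",
    "threshold",
    "thresholds",
    "tvd_curve",
    "tvd_slope",
]

CUED = "cued"
NONCUED = "non-cued"
HIGH = "high"
LOW = "low"


class NoThresholdError(ValueError):
    """The d' criterion is not attained anywhere inside the search bracket."""


class ModelDomainError(ValueError):
    """The response function is evaluated outside its domain (e.g. 0/0)."""


@dataclass(frozen=True)
class Condition:
    """One cell of the 2 (cueing) x 2 (axial salience) design."""

    cue: str
    salience: str

    def __post_init__(self) -> None:
        if self.cue not in (CUED, NONCUED):
            raise ValueError(f"cue must be {CUED!r} or {NONCUED!r}, got {self.cue!r}")
        if self.salience not in (HIGH, LOW):
            raise ValueError(
                f"salience must be {HIGH!r} or {LOW!r}, got {self.salience!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.cue}/{self.salience}"


CONDITIONS: tuple[Condition, ...] = (
    Condition(CUED, HIGH),
    Condition(CUED, LOW),
    Condition(NONCUED, HIGH),
    Condition(NONCUED, LOW),
)


@dataclass
class ChannelParams:
    """Sensitivity and gain-control parameters of the channel response.

    ``s_et`` maps (cue, salience) to the excitatory sensitivity to the
    symmetric component; ``s_it`` maps salience to the target's divisive
    self-inhibition weight.  ``s_eb``/``s_ib`` are the corresponding
    weights for the random component, shared across conditions.
    ``z_prime`` is the additive denominator constant absorbing the
    internal-noise variance; ``p`` and ``q`` are the excitatory and
    inhibitory exponents (``q`` is conventionally fixed at 2).

    ``grouping`` selects the denominator form: ``"separate"`` (canonical)
    uses (s_it*Dt)**q + (s_ib*Db)**q + z'; ``"summed"`` uses
    (s_it*Dt + s_ib*Db)**q + z' and is retained for sensitivity analysis.
    """

    s_et: Mapping[tuple[str, str], float]
    s_eb: float
    s_it: Mapping[str, float]
    s_ib: float
    z_prime: float
    p: float
    q: float = 2.0
    grouping: str = "separate"

    def __post_init__(self) -> None:
        for key, value in dict(self.s_et).items():
            if value < 0:
                raise ValueError(f"s_et[{key!r}] must be >= 0, got {value}")
        for key, value in dict(self.s_it).items():
            if value < 0:
                raise ValueError(f"s_it[{key!r}] must be >= 0, got {value}")
        if self.s_eb < 0 or self.s_ib < 0 or self.z_prime < 0:
            raise ValueError("sensitivities and z_prime must be >= 0")
        if self.p <= 0:
            raise ValueError(f"p must be > 0, got {self.p}")
        if self.grouping not in ("separate", "summed"):
            raise ValueError(f"unknown grouping {self.grouping!r}")

    def ablate(self, component: str) -> "ChannelParams":
        """Return a copy with one denominator component removed.

        ``component`` is ``"z_prime"`` (drop the additive constant) or
        ``"s_it"`` (drop the target self-inhibition, both saliences).
        """
        if component == "z_prime":
            return replace(self, z_prime=0.0)
        if component == "s_it":
            return replace(self, s_it={HIGH: 0.0, LOW: 0.0})
        raise ValueError(f"unknown ablation {component!r}")

    def copy(self) -> "ChannelParams":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class DecisionConfig:
    """Decision-stage constants: m monitored channels, n responding
    channels, gamma = SD(max of m)/SD(single), and the d' criterion."""

    m: int = 1
    n: int = 1
    gamma: float = 1.0
    dprime_criterion: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.m):
            raise ValueError(f"need 1 <= n <= m, got n={self.n}, m={self.m}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.dprime_criterion <= 0:
            raise ValueError("dprime_criterion must be positive")

    @classmethod
    def for_condition(cls, condition: Condition, dprime_criterion: float = 1.0) -> "DecisionConfig":
        """Canonical constants: cued -> (m=1, n=1, gamma=1);
        non-cued -> (m=4, n=1, gamma=0.71)."""
        if condition.cue == CUED:
            return cls(m=1, n=1, gamma=1.0, dprime_criterion=dprime_criterion)
        return cls(m=4, n=1, gamma=0.71, dprime_criterion=dprime_criterion)


# Fitted per-observer parameter sets (used as canonical test inputs).
def _params(et_cl, et_nh, et_nl, eb, it_h, it_l, ib, z, p) -> ChannelParams:
    return ChannelParams(
        s_et={
            (CUED, HIGH): 1000.0,
            (CUED, LOW): et_cl,
            (NONCUED, HIGH): et_nh,
            (NONCUED, LOW): et_nl,
        },
        s_eb=eb,
        s_it={HIGH: it_h, LOW: it_l},
        s_ib=ib,
        z_prime=z,
        p=p,
    )


# Illustration set with a pronounced double corner: the TvD slope rises
# once where the external-noise term overtakes z' and again where the
# target self-inhibition overtakes the external noise.
DOUBLE_CORNER_PARAMS = _params(1000.0, 1000.0, 1000.0, 0.5, 600.0, 600.0,
                               2000.0, 2.0, 1.8)

TABLE1_PARAMS: dict[str, ChannelParams] = {
    "CC": _params(401.0, 540.0, 201.0, 1.68, 890.0, 60.0, 1196.0, 0.15, 2.17),
    "LY": _params(443.0, 466.0, 268.0, 270.0, 850.0, 750.0, 2007.0, 0.03, 2.23),
    "TR": _params(867.0, 528.0, 416.0, 0.10, 400.0, 260.0, 7132.0, 3.54, 2.60),
    "HP": _params(477.0, 549.0, 362.0, 247.0, 1060.0, 780.0, 15219.0, 2145.0, 2.91),
}


def excitation(se: float, density):
    """Linear excitation of a symmetry processor: sensitivity times density."""
    density = np.asarray(density, dtype=float)
    if se < 0:
        raise ValueError(f"sensitivity must be >= 0, got {se}")
    if np.any(density < 0):
        raise ValueError("density must be >= 0")
    return se * density


def channel_response(d_sym, d_rand, params: ChannelParams, condition: Condition):
    """Response of the channel tuned to the presented axis.

    Excitation (s_et*D_sym + s_eb*D_rand)**p divided by the gain-control
    denominator selected by ``params.grouping``.  Accepts scalars or
    broadcastable arrays of densities.
    """
    d_sym = np.asarray(d_sym, dtype=float)
    d_rand = np.asarray(d_rand, dtype=float)
    if np.any(d_sym < 0) or np.any(d_rand < 0):
        raise ValueError("densities must be >= 0")
    s_et = params.s_et[(condition.cue, condition.salience)]
    s_it = params.s_it[condition.salience]
    num = (s_et * d_sym + params.s_eb * d_rand) ** params.p
    if params.grouping == "separate":
        den = (s_it * d_sym) ** params.q + (params.s_ib * d_rand) ** params.q + params.z_prime
    else:
        den = (s_it * d_sym + params.s_ib * d_rand) ** params.q + params.z_prime
    if np.any((np.asarray(den) == 0) & (np.asarray(num) == 0)):
        raise ModelDomainError(
            "0/0 response: z_prime = 0 with zero stimulus densities"
        )
    out = num / den
    return out if out.ndim else float(out)


def control_response(d_t, d_b, params: ChannelParams, condition: Condition):
    """Response to the density-matched non-symmetric stimulus.

    The control pattern carries the same total dot count as target+masker,
    so the channel sees a purely random component of density D_t + D_b.
    """
    d_t = np.asarray(d_t, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    return channel_response(np.zeros_like(d_t + d_b), d_t + d_b, params, condition)


def pooled_response(r_responding, r_nonresponding, m: int, n: int):
    """Fourth-power summation approximating the mean of the max of m
    channels, n of which respond to the symmetric component."""
    if not (1 <= n <= m):
        raise ValueError(f"need 1 <= n <= m, got n={n}, m={m}")
    r_responding = np.asarray(r_responding, dtype=float)
    r_nonresponding = np.asarray(r_nonresponding, dtype=float)
    out = (n * r_responding**4 + (m - n) * r_nonresponding**4) ** 0.25
    return out if out.ndim else float(out)


def dprime(d_t, d_b, params: ChannelParams, condition: Condition,
           decision: DecisionConfig | None = None):
    """Decision-stage d' for target density d_t on masker density d_b.

    In the target interval the n responding channels see the symmetric
    component while the m-n mismatched channels respond as if the image
    were purely random at the same total density; in the control interval
    all m channels see the density-matched random pattern.  The pooled
    difference is divided by gamma, the max-distribution SD factor
    (response-scale noise SD is normalized to 1).
    """
    if decision is None:
        decision = DecisionConfig.for_condition(condition)
    r_target = channel_response(d_t, d_b, params, condition)
    r_control = control_response(d_t, d_b, params, condition)
    pooled_t = pooled_response(r_target, r_control, decision.m, decision.n)
    pooled_c = pooled_response(r_control, r_control, decision.m, decision.n)
    out = (pooled_t - pooled_c) / decision.gamma
    return out


_BRACKET = (1e-6, 1.0)


def thresholds(d_b, params: ChannelParams, condition: Condition,
               decision: DecisionConfig | None = None,
               bracket: tuple[float, float] = _BRACKET,
               n_scan: int = 121, n_bisect: int = 45,
               on_fail: str = "raise") -> np.ndarray:
    """Vectorized threshold solver over an array of masker densities.

    Scans a log-spaced grid of target densities for the first crossing of
    the d' criterion, then bisects on log10 D_t.  Returns the upper edge
    of the final bracket (the smallest grid density attaining the
    criterion).  ``on_fail="nan"`` returns NaN where the criterion is
    never reached instead of raising :class:`NoThresholdError`.
    """
    if decision is None:
        decision = DecisionConfig.for_condition(condition)
    d_b = np.atleast_1d(np.asarray(d_b, dtype=float))
    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    crit = decision.dprime_criterion

    grid = np.logspace(lo, hi, n_scan)
    dp = dprime(grid[:, None], d_b[None, :], params, condition, decision)
    above = dp >= crit
    reached = above.any(axis=0)
    if not reached.all() and on_fail == "raise":
        bad = d_b[~reached]
        raise NoThresholdError(
            f"d' criterion {crit} not reached within D_t bracket {bracket} "
            f"for masker densities {bad}"
        )
    first = np.where(reached, above.argmax(axis=0), n_scan - 1)

    log_grid = np.linspace(lo, hi, n_scan)
    hi_log = log_grid[first]
    lo_log = log_grid[np.maximum(first - 1, 0)]
    # cells already above criterion at the bracket floor resolve to the floor
    at_floor = first == 0

    for _ in range(n_bisect):
        mid = 0.5 * (lo_log + hi_log)
        dp_mid = dprime(10.0**mid, d_b, params, condition, decision)
        take_hi = dp_mid >= crit
        hi_log = np.where(take_hi, mid, hi_log)
        lo_log = np.where(take_hi, lo_log, mid)

    out = 10.0**hi_log
    out[at_floor] = bracket[0]
    out[~reached] = np.nan
    return out


def threshold(d_b: float, params: ChannelParams, condition: Condition,
              decision: DecisionConfig | None = None,
              bracket: tuple[float, float] = _BRACKET) -> float:
    """Smallest target density at which d' reaches the criterion."""
    return float(thresholds(d_b, params, condition, decision, bracket=bracket)[0])


@dataclass
class TvDDataset:
    """Per-condition masker-density -> target-threshold table.

    Backed by a DataFrame with columns ``condition_cue``,
    ``condition_salience``, ``masker_density``, ``threshold_density``,
    ``se``.  Masker density may be 0 (unmasked); thresholds are positive.
    """

    table: pd.DataFrame

    COLUMNS = ("condition_cue", "condition_salience", "masker_density",
               "threshold_density", "se")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"TvD table missing columns {sorted(missing)}")
        t = self.table
        if ((t["masker_density"] < 0) | (t["masker_density"] > 1)).any():
            raise ValueError("masker densities must lie in [0, 1]")
        if ((t["threshold_density"] <= 0) | (t["threshold_density"] > 1)).any():
            raise ValueError("threshold densities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, condition: Condition) -> "TvDDataset":
        t = self.table
        sel = (t["condition_cue"] == condition.cue) & (
            t["condition_salience"] == condition.salience
        )
        return TvDDataset(t[sel].reset_index(drop=True))

    def conditions(self) -> list[Condition]:
        pairs = self.table[["condition_cue", "condition_salience"]].drop_duplicates()
        return [Condition(c, s) for c, s in pairs.itertuples(index=False)]

    @property
    def log10_view(self) -> pd.DataFrame:
        """Log10 densities; rows with masker_density == 0 get NaN abscissa."""
        t = self.table.copy()
        with np.errstate(divide="ignore"):
            t["log10_masker"] = np.where(
                t["masker_density"] > 0, np.log10(t["masker_density"]), np.nan
            )
        t["log10_threshold"] = np.log10(t["threshold_density"])
        return t

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "TvDDataset":
        return cls(pd.read_csv(path))

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[Condition, float, float, float]]) -> "TvDDataset":
        recs = [
            {
                "condition_cue": cond.cue,
                "condition_salience": cond.salience,
                "masker_density": db,
                "threshold_density": dt,
                "se": se,
            }
            for cond, db, dt, se in rows
        ]
        return cls(pd.DataFrame.from_records(recs))


def tvd_curve(params: ChannelParams, condition: Condition,
              d_b_grid: Sequence[float],
              decision: DecisionConfig | None = None,
              ablate: str | None = None) -> TvDDataset:
    """Model TvD curve: threshold at every masker density in the grid.

    ``ablate`` optionally removes one denominator component
    (``"z_prime"`` or ``"s_it"``) before solving.
    """
    if ablate is not None:
        params = params.ablate(ablate)
    d_b = np.asarray(list(d_b_grid), dtype=float)
    thr = thresholds(d_b, params, condition, decision)
    return TvDDataset.from_rows(
        (condition, float(db), float(t), 0.0) for db, t in zip(d_b, thr)
    )


def tvd_slope(dataset: TvDDataset, density_range: tuple[float, float] | None = None,
              condition: Condition | None = None) -> float:
    """Least-squares slope of log10 threshold vs log10 masker density.

    Rows with masker_density == 0 are excluded (no log abscissa); the
    optional ``density_range`` restricts to masker densities inside the
    closed interval.
    """
    if condition is not None:
        dataset = dataset.subset(condition)
    t = dataset.table
    sel = t["masker_density"] > 0
    if density_range is not None:
        lo, hi = density_range
        sel &= (t["masker_density"] >= lo) & (t["masker_density"] <= hi)
    t = t[sel]
    if len(t) < 2:
        raise ValueError("need at least 2 points with positive masker density")
    x = np.log10(t["masker_density"].to_numpy())
    y = np.log10(t["threshold_density"].to_numpy())
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
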