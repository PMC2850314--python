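"""Rival accounts of the cueing effect, and the Gaussian order-statistic
constants used by the decision stage.

Two baselines are implemented: the max-of-m Gaussian uncertainty account
(cueing removes channel uncertainty) and the signal-to-noise /
weight-of-evidence account (required evidence scales with the number of
candidate axis orientations, predicting an m-fold threshold factor and a
unit TvD slope).
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "max_gaussian_moments",
    "mean_max_shifted",
    "max_gaussian_sd_ratio",
    "uncertainty_threshold_ratio",
    "weight_of_evidence_ratio",
    "snr_predicted_slope",
    "compare_slope_null",
]

_PHI = stats.norm.pdf
_CDF = stats.norm.cdf


def max_gaussian_moments(m: int) -> tuple[float, float]:
    """Mean and SD of the maximum of m i.i.d. standard Gaussians, by
    order-statistic quadrature."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")

    def moment(k: int) -> float:
        f = lambda x: x**k * m * _PHI(x) * _CDF(x) ** (m - 1)
        return integrate.quad(f, -12, 12)[0]

    e1, e2 = moment(1), moment(2)
    return e1, float(np.sqrt(e2 - e1**2))


def mean_max_shifted(delta: float, m: int) -> float:
    """E[max(delta + Z0, Z1, ..., Z_{m-1})] for i.i.d. standard Gaussians.

    With delta = 0 this is the mean of the max of m standard normals.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m == 1:
        return float(delta)

    def f(y):
        density = _PHI(y - delta) * _CDF(y) ** (m - 1) + (m - 1) * _PHI(y) * _CDF(
            y
        ) ** (m - 2) * _CDF(y - delta)
        return y * density

    return integrate.quad(f, -12, 14 + max(delta, 0))[0]


def max_gaussian_sd_ratio(m: int, method: str = "quadrature",
                          n_samples: int = 1_000_000, seed=None) -> float:
    """SD(max of m i.i.d. standard Gaussians) / SD(one sample).

    ``method="quadrature"`` integrates the order-statistic density;
    ``method="monte_carlo"`` estimates from ``n_samples`` maxima.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if method == "quadrature":
        return max_gaussian_moments(m)[1]
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        maxima = rng.standard_normal((n_samples, m)).max(axis=1)
        return float(maxima.std(ddof=1))
    raise ValueError(f"unknown method {method!r}")


def _pc_target(dprime_target: float, pc_mapping: str) -> float:
    """Percent correct a single channel achieves at the target d'."""
    if dprime_target <= 0:
        raise ValueError("dprime_target must be positive")
    if pc_mapping == "yesno":       # unbiased yes/no
        return float(_CDF(dprime_target / 2.0))
    if pc_mapping == "2afc":        # two-interval forced choice
        return float(_CDF(dprime_target / np.sqrt(2.0)))
    raise ValueError(f"unknown pc_mapping {pc_mapping!r}")


def _pc_max_rule_quad(delta: float, m: int) -> float:
    """P(max of {delta+Z0, Z1..Z_{m-1}} > max of m independent Z), by
    quadrature over the density of the comparison max."""
    f = lambda y: (1.0 - _CDF(y - delta) * _CDF(y) ** (m - 1)) * m * _PHI(y) * _CDF(y) ** (m - 1)
    return integrate.quad(f, -12, 14)[0]


def uncertainty_threshold_ratio(m: int, dprime_target: float = 1.0,
                                method: str = "monte_carlo",
                                n_samples: int = 1_000_000, seed=0,
                                pc_mapping: str = "yesno") -> float:
    """Signal-intensity multiple a max-of-m observer needs, relative to a
    single-channel observer, to keep the same performance.

    Performance is equated on the proportion correct of the equivalent
    two-interval comparison (signal interval: max of one shifted and m-1
    unshifted channels; comparison interval: max of m unshifted
    channels), at the percent-correct level a single channel reaches at
    ``dprime_target`` under ``pc_mapping`` ("yesno": Phi(d'/2), the
    package's yes/no convention; "2afc": Phi(d'/sqrt(2))).

    Monte Carlo exploits that a trial is correct iff the shift exceeds a
    per-trial critical value, so the required shift is a quantile of the
    simulated critical values.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    pc = _pc_target(dprime_target, pc_mapping)
    # single-channel shift at the same performance level (closed form:
    # the two-interval comparison of two unit Gaussians has SD sqrt(2))
    delta_single = float(np.sqrt(2.0) * stats.norm.ppf(pc))
    if m == 1:
        return 1.0

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal(n_samples)
        m1 = rng.standard_normal((n_samples, m - 1)).max(axis=1)
        m2 = rng.standard_normal((n_samples, m)).max(axis=1)
        # correct iff m1 > m2 (already winning) or delta + z0 > m2
        crit = np.where(m1 > m2, -np.inf, m2 - z0)
        delta_m = float(np.quantile(crit, pc))
    elif method == "quadrature":
        delta_m = float(optimize.brentq(
            lambda d: _pc_max_rule_quad(d, m) - pc, 1e-9, 20.0, xtol=1e-10,
        ))
    else:
        raise ValueError(f"unknown method {method!r}")
    return delta_m / delta_single


def weight_of_evidence_ratio(n_orientations: int) -> float:
    """Threshold factor under the signal-to-noise account: required
    evidence, hence threshold, scales with the number of candidate axis
    orientations inspected."""
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    return float(n_orientations)


def snr_predicted_slope() -> float:
    """Log-log TvD slope predicted by the signal-to-noise account."""
    return 1.0


def compare_slope_null(masker_density, threshold_density,
                       null_slope: float = 1.0,
                       alt_slope: float = 0.75) -> dict:
    """Compare fixed-slope power-law fits to TvD data in log-log space.

    Each fit is a line of fixed slope with a least-squares intercept on
    log10 threshold vs log10 masker density.  Returns both SSEs and their
    ratio (alt / null); a ratio well below 1 rejects the unit-slope null.
    """
    x = np.log10(np.asarray(masker_density, dtype=float))
    y = np.log10(np.asarray(threshold_density, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 points")

    def sse(slope: float) -> float:
        intercept = np.mean(y - slope * x)
        return float(np.sum((y - slope * x - intercept) ** 2))

    sse_null, sse_alt = sse(null_slope), sse(alt_slope)
    return {
        "null_slope": null_slope,
        "alt_slope": alt_slope,
        "sse_null": sse_null,
        "sse_alt": sse_alt,
        "sse_ratio": sse_alt / sse_null if sse_null > 0 else np.inf,
        "prefers_alt": sse_alt < sse_null,
    }
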