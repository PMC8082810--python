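"""Moment-matched positive distributions for the synthetic cohort.

Published summaries give only mean +/- SD per group and visit, so each
variable is simulated from a two-parameter positive family whose *realized*
moments equal the targets:

* zero-truncated (or doubly truncated) normal, with the parent ``(mu, sigma)``
  solved numerically so that the truncated distribution itself has the target
  mean and SD.  A truncated-at-zero normal cannot exceed a coefficient of
  variation of ~1, so
* heavily dispersed positive variables (CV near or above 1) use a
  moment-matched lognormal instead.

Both families are sampled through a Gaussian copula: a standard-normal score
``z`` is mapped through the matched quantile function, which preserves the
marginal exactly whatever the correlation structure of the ``z``'s.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "trunc_normal_params",
    "trunc_normal_from_z",
    "lognormal_params",
    "lognormal_from_z",
]


@lru_cache(maxsize=None)
def trunc_normal_params(
    mean: float, sd: float, lower: float = 0.0, upper: float = math.inf
) -> tuple[float, float]:
    """Parent ``(mu, sigma)`` whose [lower, upper]-truncation has the given moments.

    Raises ``ValueError`` when no truncated normal can realize the target
    (for zero-truncation this happens as the CV approaches 1).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")

    def resid(p):
        mu, log_s = p
        s = math.exp(log_s)
        a, b = (lower - mu) / s, (upper - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    starts = [
        (mean, math.log(sd)),
        (mean - 0.5 * sd, math.log(1.2 * sd)),
        (mean - 1.5 * sd, math.log(2.0 * sd)),
        (lower if math.isfinite(lower) else 0.0, math.log(2.5 * sd)),
        (-2.0 * sd, math.log(3.5 * sd)),
    ]
    for x0 in starts:
        with np.errstate(all="ignore"):
            sol = optimize.root(resid, x0, method="hybr")
        if sol.success and max(abs(r) for r in resid(sol.x)) < 1e-8 * max(mean, sd, 1):
            return float(sol.x[0]), float(math.exp(sol.x[1]))
    raise ValueError(
        f"no truncated normal on [{lower}, {upper}] has mean={mean}, sd={sd} "
        "(coefficient of variation too large?)"
    )


def trunc_normal_from_z(
    z, mean: float, sd: float, lower: float = 0.0, upper: float = math.inf
):
    """Map standard-normal copula scores to the moment-matched truncated normal."""
    mu, s = trunc_normal_params(mean, sd, lower, upper)
    a, b = (lower - mu) / s, (upper - mu) / s
    u = stats.norm.cdf(np.asarray(z, dtype=float))
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=s)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """``(mu, sigma)`` of log-value for a lognormal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal targets must be positive")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def lognormal_from_z(z, mean: float, sd: float):
    """Map standard-normal copula scores to the moment-matched lognormal."""
    mu, s = lognormal_params(mean, sd)
    return np.exp(mu + s * np.asarray(z, dtype=float))
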