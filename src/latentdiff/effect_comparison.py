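"""Observed vs. latent Cohen's d for one scale: discrepancy statistics.

The observed effect d_Y is the classical Cohen's d on the (reverse-keyed,
summed or averaged) scale score; the latent effect d_tau comes from the
multigroup CFA.  Their discrepancy is summarized in magnitude terms:
signed_delta_d = |d_tau| - |d_Y|, positive when stripping measurement error
enlarges the standardized difference, as classical test theory predicts.
The sampling variance of each d uses

    var(d) = (n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2))

and the one-tailed z test treats the two estimates as independent (they share
a sample, so the variance of the difference is, if anything, overstated and
the test conservative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "EffectEstimate",
    "EffectComparison",
    "cohens_d_observed",
    "d_variance",
    "compare_ds",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A standardized mean difference with its sampling variance."""

    d: float
    n1: int
    n2: int
    var_d: float

    @classmethod
    def from_d(cls, d: float, n1: int, n2: int) -> "EffectEstimate":
        return cls(d=d, n1=n1, n2=n2, var_d=d_variance(d, n1, n2))


@dataclass(frozen=True)
class EffectComparison:
    """One scale's observed/latent effect comparison (one report row).

    percent_change is None when both effects are exactly zero (the symmetric
    denominator vanishes and the relative change is undefined).
    """

    d_tau: EffectEstimate
    d_Y: EffectEstimate
    delta_d: float
    signed_delta_d: float
    percent_change: float | None
    signed_percent_change: float | None
    z: float
    p_one_tailed: float
    ci_low: float
    ci_high: float
    omega: float | None = None


def d_variance(d: float, n1: int, n2: int) -> float:
    """Sampling variance of Cohen's d: (n1+n2)/(n1 n2) + d^2/(2(n1+n2))."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    return (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))


def cohens_d_observed(scores, groups) -> EffectEstimate:
    """Cohen's d of an observed score between two groups.

    d = (mean1 - mean2) / pooled SD, where 'group 1' is the first group label
    in sorted order and the pooled SD uses (n-1) weights.  Scale-free, so sum
    versus mean scoring makes no difference.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(np.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    x1 = scores[groups == levels[0]]
    x2 = scores[groups == levels[1]]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    sd_pool = math.sqrt(((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2))
    if sd_pool == 0:
        raise ValueError("pooled SD is zero; d undefined")
    d = (x1.mean() - x2.mean()) / sd_pool
    return EffectEstimate.from_d(float(d), n1, n2)


def compare_ds(
    d_tau: EffectEstimate, d_Y: EffectEstimate, omega: float | None = None
) -> EffectComparison:
    """Discrepancy statistics between a latent and an observed d.

    signed_delta_d = |d_tau| - |d_Y|; delta_d is its absolute value; percent
    change uses the symmetric mean-of-magnitudes denominator
    (|d_tau| + |d_Y|)/2.  The z statistic divides signed_delta_d by the root
    of the summed sampling variances; the one-tailed p tests the expectation
    that the latent effect exceeds the observed one in magnitude; the 95% CI
    is signed_delta_d +/- 1.96 SE.
    """
    sdd = abs(d_tau.d) - abs(d_Y.d)
    dd = abs(sdd)
    denom = (abs(d_tau.d) + abs(d_Y.d)) / 2.0
    if denom == 0:
        pct = spct = None
    else:
        pct = 100.0 * dd / denom
        spct = 100.0 * sdd / denom
    se = math.sqrt(d_tau.var_d + d_Y.var_d)
    z = sdd / se
    p = float(norm.sf(z))
    half = 1.959963984540054 * se
    return EffectComparison(
        d_tau=d_tau,
        d_Y=d_Y,
        delta_d=dd,
        signed_delta_d=sdd,
        percent_change=pct,
        signed_percent_change=spct,
        z=z,
        p_one_tailed=p,
        ci_low=sdd - half,
        ci_high=sdd + half,
        omega=omega,
    )
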