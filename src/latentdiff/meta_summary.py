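"""Random-effects meta-analysis of per-scale effect-size discrepancies.

Each scale contributes a discrepancy estimate (absolute or signed delta-d)
with a known sampling variance; the random-effects model treats the true
per-scale discrepancies as Normal(mu, tau^2).  tau^2 is estimated by REML
(profile maximization, the default) or DerSimonian-Laird moments; Cochran's Q
uses fixed-effect weights 1/v_i; I^2 relates tau^2 to a typical within-scale
variance.  Because tau is on the same scale as delta-d itself, the fitted
normal distribution also answers exceedance questions ("what fraction of
scales should show a discrepancy beyond c?").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "MetaResult",
    "CorrelationResult",
    "random_effects_meta",
    "exceedance_probability",
    "reliability_discrepancy_correlation",
]


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    tau: float
    k: int
    method: str


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    df: int
    kind: str


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    q = float(w @ (y - (w @ y) / w.sum()) ** 2)
    c = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (q - (len(y) - 1)) / c)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    def neg_restricted_ll(tau2):
        wi = 1.0 / (v + tau2)
        mu = (wi @ y) / wi.sum()
        return 0.5 * (
            -np.sum(np.log(wi)) + np.log(wi.sum()) + float(wi @ (y - mu) ** 2)
        )

    upper = max(10.0 * float(np.var(y)), 10.0 * float(v.max()), 1e-6)
    res = minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    return max(0.0, float(res.x))


def random_effects_meta(effects, variances, method: str = "REML") -> MetaResult:
    """Pool per-scale effects under the random-effects model.

    Q is computed with fixed-effect weights 1/v_i (Cochran's Q); the pooled
    estimate uses weights 1/(v_i + tau^2); I^2 = 100 tau^2/(tau^2 + v_typ)
    with v_typ = (k-1) sum(w) / ((sum w)^2 - sum w^2).
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("effects and variances must be equal-length vectors")
    k = len(y)
    if k < 2:
        raise ValueError("meta-analysis needs at least 2 effects")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")

    w_fe = 1.0 / v
    mu_fe = (w_fe @ y) / w_fe.sum()
    q = float(w_fe @ (y - mu_fe) ** 2)
    df = k - 1
    p_q = float(chi2.sf(q, df))

    method = method.upper()
    if method == "DL":
        tau2 = _dl_tau2(y, v)
    elif method == "REML":
        tau2 = _reml_tau2(y, v)
    else:
        raise ValueError("method must be 'REML' or 'DL'")

    w = 1.0 / (v + tau2)
    pooled = float((w @ y) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    zcrit = 1.959963984540054
    z = pooled / se
    p = float(2.0 * norm.sf(abs(z)))
    v_typ = df * w_fe.sum() / (w_fe.sum() ** 2 - (w_fe**2).sum())
    i2 = 100.0 * tau2 / (tau2 + v_typ)
    return MetaResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - zcrit * se,
        ci_high=pooled + zcrit * se,
        p=p,
        q=q,
        df=df,
        p_q=p_q,
        i2=float(i2),
        tau2=float(tau2),
        tau=float(np.sqrt(tau2)),
        k=k,
        method=method,
    )


def exceedance_probability(pooled: float, tau: float, cutoff: float) -> float:
    """Percent of scales expected beyond ``cutoff`` under Normal(pooled, tau^2).

    The between-scale SD tau is in the same metric as the effect itself, so
    the fitted random-effects distribution directly yields tail fractions.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(100.0 * norm.sf((cutoff - pooled) / tau))


def reliability_discrepancy_correlation(
    omegas, discrepancies, kind: str = "pearson"
) -> CorrelationResult:
    """Correlate per-scale reliability with discrepancy magnitude.

    Pearson or Spearman coefficient with a Fisher-z 95% CI and a two-sided
    normal-approximation p value.  For Spearman the Fisher-z interval is
    applied to the rank correlation — a common approximation.
    """
    x = np.asarray(omegas, dtype=float)
    y = np.asarray(discrepancies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    kind = kind.lower()
    if kind == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif kind != "pearson":
        raise ValueError("kind must be 'pearson' or 'spearman'")
    r = float(np.corrcoef(x, y)[0, 1])
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    sz = 1.0 / np.sqrt(n - 3)
    zcrit = 1.959963984540054
    lo, hi = np.tanh(zr - zcrit * sz), np.tanh(zr + zcrit * sz)
    p = float(2.0 * norm.sf(abs(zr) / sz))
    return CorrelationResult(
        r=r, ci_low=float(lo), ci_high=float(hi), p=p, df=n - 2, kind=kind
    )
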