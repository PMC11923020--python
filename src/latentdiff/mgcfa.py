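"""Invariance-constrained two-group ordinal one-factor CFA.

The model: each item's observed category is a thresholded view of a normal
latent item response that loads on a single latent trait.  Thresholds and
loadings are constrained equal across the two groups (the scalar-invariance
assumption implicit in comparing raw scale scores); the group-2 latent mean
``alpha2`` and variance ``psi2`` are free, with group 1 fixed at 0 and 1 for
identification.  Item intercepts are fixed at zero in both groups — for
ordinal items the thresholds carry all location information, so intercept
equality holds trivially.

Identification uses the delta parameterization: latent item responses are
standardized in group 1, so group-1 residual variances are 1 - lambda^2 and
the group-2 latent-response scale s_i = sqrt(1 + lambda_i^2 (psi2 - 1))
absorbs the variance shift.  Estimation is two-stage least squares on summary
statistics: per-group thresholds and polychoric correlations are estimated
first, then the parameters minimize

    sum_g (s_g - sigma_g(params))' W_g^-1 (s_g - sigma_g(params))

with W_g diagonal — identity for ULS, or jackknife-estimated sampling
variances of the summary statistics for DWLS.  Point estimates are consistent
under either weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .polychoric import _thresholds_indexed, polychoric_corr, polychoric_matrix
from .synthetic_data import ItemResponseData

__all__ = [
    "MGCFAParams",
    "MGCFAFit",
    "GroupStats",
    "HeywoodError",
    "ConvergenceError",
    "compute_group_stats",
    "implied_group_stats",
    "fit_invariant_mgcfa",
    "latent_d",
    "mcdonald_omega",
]

LAMBDA_BOUND = 0.999
# loadings within this distance of the bound imply a (near-)non-positive
# residual variance in the delta parameterization: a Heywood case
HEYWOOD_MARGIN = 1e-3


class HeywoodError(RuntimeError):
    """Improper solution: implied residual variance at or below zero."""

    def __init__(self, items: Sequence[str], loadings: Sequence[float]):
        self.items = tuple(items)
        self.loadings = tuple(float(x) for x in loadings)
        super().__init__(
            f"Heywood condition: residual variance non-positive for items "
            f"{list(self.items)} (|loading| at bound)"
        )


class ConvergenceError(RuntimeError):
    """The discrepancy minimization did not converge."""


@dataclass(frozen=True)
class MGCFAParams:
    """Estimated parameters of the invariant two-group model.

    ``thresholds`` maps item name to (cut indices, values) on the group-1
    standardized latent-response scale; ``residual_variances`` are the
    group-1 (delta-parameterization) uniquenesses 1 - lambda^2, shared in the
    raw metric by group 2.
    """

    item_names: tuple[str, ...]
    loadings: np.ndarray
    thresholds: dict[str, tuple[np.ndarray, np.ndarray]]
    alpha2: float
    psi2: float

    @property
    def residual_variances(self) -> np.ndarray:
        return 1.0 - self.loadings**2


@dataclass(frozen=True)
class MGCFAFit:
    params: MGCFAParams
    discrepancy: float
    converged: bool
    n_iter: int
    n1: int
    n2: int
    estimator: str
    group_levels: tuple

    def to_dict(self) -> dict:
        p = self.params
        return {
            "loadings": {k: float(v) for k, v in zip(p.item_names, p.loadings)},
            "alpha2": p.alpha2,
            "psi2": p.psi2,
            "discrepancy": self.discrepancy,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n1": self.n1,
            "n2": self.n2,
            "estimator": self.estimator,
        }


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics for one group: thresholds and polychorics."""

    n: int
    thr_idx: dict[str, np.ndarray]
    thr_val: dict[str, np.ndarray]
    corr: np.ndarray  # item x item polychoric matrix


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def _group_stats_from_responses(resp: np.ndarray, items, n_cat: int) -> GroupStats:
    thr_idx, thr_val = {}, {}
    for j, item in enumerate(items):
        counts = np.bincount(resp[:, j], minlength=n_cat)
        idx, val = _thresholds_indexed(counts, item=item)
        thr_idx[item], thr_val[item] = idx, val
    m = len(items)
    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            table = np.zeros((n_cat, n_cat))
            np.add.at(table, (resp[:, i], resp[:, j]), 1.0)
            rows = table.sum(axis=1) > 0
            cols = table.sum(axis=0) > 0
            est = polychoric_corr(table[np.ix_(rows, cols)], thr_val[items[i]], thr_val[items[j]])
            corr[i, j] = corr[j, i] = est.rho
    return GroupStats(n=resp.shape[0], thr_idx=thr_idx, thr_val=thr_val, corr=corr)


def compute_group_stats(data: ItemResponseData) -> tuple[GroupStats, GroupStats]:
    items = tuple(data.scale_def.items)
    n_cat = data.scale_def.n_categories
    out = []
    for g in data.group_levels:
        resp = data.responses.loc[data.group_mask(g), list(items)].to_numpy(np.int64)
        out.append(_group_stats_from_responses(resp, items, n_cat))
    return out[0], out[1]


def _stack_stats(stats: GroupStats, items) -> np.ndarray:
    """Fixed ordering: all thresholds item by item, then lower-triangle corrs."""
    parts = [stats.thr_val[item] for item in items]
    m = len(items)
    iu = np.triu_indices(m, k=1)
    parts.append(stats.corr[iu])
    return np.concatenate(parts)


def _jackknife_weights(
    resp: np.ndarray, items, n_cat: int, ref_idx: dict, n_blocks: int = 20
) -> np.ndarray:
    """DWLS diagonal weights: inverse delete-a-block jackknife variances.

    Blocks are contiguous runs of respondents (rows are exchangeable).  Cuts
    unobserved in a replicate inherit the full-sample value, which only makes
    the variance estimate conservative for rarely-hit thresholds.
    """
    n = resp.shape[0]
    n_blocks = min(n_blocks, n)
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    reps = []
    for b in range(n_blocks):
        keep = np.ones(n, dtype=bool)
        keep[bounds[b] : bounds[b + 1]] = False
        sub = resp[keep]
        stats_b = _group_stats_from_responses(sub, items, n_cat)
        # align replicate thresholds to the full-sample cut structure
        parts = []
        for item in items:
            full_idx = ref_idx[item]
            vals = np.full(len(full_idx), np.nan)
            pos = {k: i for i, k in enumerate(stats_b.thr_idx[item])}
            for i, k in enumerate(full_idx):
                if k in pos:
                    vals[i] = stats_b.thr_val[item][pos[k]]
            parts.append(vals)
        m = len(items)
        iu = np.triu_indices(m, k=1)
        parts.append(stats_b.corr[iu])
        reps.append(np.concatenate(parts))
    reps = np.asarray(reps)
    mean = np.nanmean(reps, axis=0)
    var_jack = (n_blocks - 1) / n_blocks * np.nansum((reps - mean) ** 2, axis=0)
    var_jack = np.maximum(var_jack, 1e-10)
    return 1.0 / var_jack


# ---------------------------------------------------------------------------
# model-implied statistics
# ---------------------------------------------------------------------------


def implied_group_stats(
    lam: np.ndarray,
    thr: list[np.ndarray],
    alpha2: float,
    psi2: float,
    group: int,
    thr_idx_order: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Model-implied thresholds and correlations, stacked like the samples.

    group 1: thresholds as given, correlations lambda_i lambda_j.
    group 2: latent responses rescaled by s_i = sqrt(1 + lambda_i^2 (psi2-1))
    and shifted by lambda_i alpha2, so thresholds (t - lambda alpha2)/s and
    correlations lambda_i lambda_j psi2 / (s_i s_j).
    """
    m = len(lam)
    parts = []
    if group == 1:
        for t in thr:
            parts.append(t)
        scale = np.ones(m)
        corr = np.outer(lam, lam)
    else:
        scale = np.sqrt(1.0 + lam**2 * (psi2 - 1.0))
        for i, t in enumerate(thr):
            parts.append((t - lam[i] * alpha2) / scale[i])
        corr = np.outer(lam, lam) * psi2 / np.outer(scale, scale)
    iu = np.triu_indices(m, k=1)
    parts.append(corr[iu])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


def _pack(lam, thr_list, alpha2, psi2):
    x = [np.arctanh(np.clip(lam / LAMBDA_BOUND, -1 + 1e-12, 1 - 1e-12))]
    for t in thr_list:
        first = t[0]
        diffs = np.maximum(np.diff(t), 1e-4)
        x.append(np.concatenate(([first], np.log(diffs))))
    x.append([alpha2, np.log(psi2)])
    return np.concatenate(x)


def _unpack(x, m, thr_sizes):
    lam = LAMBDA_BOUND * np.tanh(x[:m])
    thr_list = []
    pos = m
    for k in thr_sizes:
        seg = x[pos : pos + k]
        thr_list.append(seg[0] + np.concatenate(([0.0], np.cumsum(np.exp(seg[1:])))))
        pos += k
    alpha2 = x[pos]
    psi2 = np.exp(np.clip(x[pos + 1], -10, 10))
    return lam, thr_list, alpha2, psi2


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _start_values(s1: GroupStats, s2: GroupStats, items):
    """Deterministic starts: principal-axis loadings from the pooled
    polychoric matrix and n-weighted average sample thresholds."""
    n1, n2 = s1.n, s2.n
    pooled = (n1 * s1.corr + n2 * s2.corr) / (n1 + n2)
    evals, evecs = np.linalg.eigh(pooled)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-3))
    if lam0.sum() < 0:
        lam0 = -lam0
    lam0 = np.clip(lam0, -0.95, 0.95)
    lam0[np.abs(lam0) < 0.05] = 0.05

    thr_union, thr0 = [], []
    for item in items:
        union = np.union1d(s1.thr_idx[item], s2.thr_idx[item])
        vals = np.zeros(len(union))
        for i, k in enumerate(union):
            num = den = 0.0
            for s in (s1, s2):
                hit = np.flatnonzero(s.thr_idx[item] == k)
                if hit.size:
                    num += s.n * s.thr_val[item][hit[0]]
                    den += s.n
            vals[i] = num / den
        # enforce strict ordering of the start
        vals = np.maximum.accumulate(vals + 1e-6 * np.arange(len(vals)))
        thr_union.append(union)
        thr0.append(vals)
    return lam0, thr_union, thr0


def fit_invariant_mgcfa(
    data: ItemResponseData,
    estimator: str = "DWLS",
    max_iter: int = 500,
    n_jackknife_blocks: int = 20,
) -> MGCFAFit:
    """Fit the invariance-constrained two-group ordinal one-factor model.

    Minimizes the (diagonally) weighted least-squares discrepancy between the
    per-group sample thresholds/polychorics and their model-implied values,
    with loadings and thresholds shared across groups and the group-2 latent
    mean and variance free.  Raises :class:`HeywoodError` when the solution
    implies a non-positive residual variance (loading at the unit bound) and
    :class:`ConvergenceError` when the optimizer fails — callers typically
    exclude the scale in the first case.
    """
    if estimator not in ("ULS", "DWLS"):
        raise ValueError("estimator must be 'ULS' or 'DWLS'")
    items = tuple(data.scale_def.items)
    if len(items) < 3:
        raise ValueError("at least 3 items are required for identification")
    n_cat = data.scale_def.n_categories
    s1, s2 = compute_group_stats(data)

    score = data.scored().to_numpy()
    g1, g2 = data.group_levels
    m1, m2 = data.group_mask(g1), data.group_mask(g2)
    sd = np.sqrt(
        ((m1.sum() - 1) * score[m1].var(ddof=1) + (m2.sum() - 1) * score[m2].var(ddof=1))
        / (m1.sum() + m2.sum() - 2)
    )
    alpha0 = float((score[m2].mean() - score[m1].mean()) / sd) if sd > 0 else 0.0

    if estimator == "DWLS":
        weights = []
        for g, ref in zip(data.group_levels, (s1, s2)):
            resp = data.responses.loc[data.group_mask(g), list(items)].to_numpy(np.int64)
            weights.append(_jackknife_weights(resp, items, n_cat, ref.thr_idx, n_jackknife_blocks))
        w1, w2 = weights
    else:
        w1 = w2 = None

    return fit_from_stats(
        s1,
        s2,
        items,
        alpha0=alpha0,
        weights=(w1, w2),
        estimator=estimator,
        max_iter=max_iter,
        group_levels=data.group_levels,
    )


def fit_from_stats(
    s1: GroupStats,
    s2: GroupStats,
    items: tuple[str, ...],
    alpha0: float = 0.0,
    weights: tuple[np.ndarray | None, np.ndarray | None] = (None, None),
    estimator: str = "ULS",
    max_iter: int = 500,
    group_levels: tuple = ("g1", "g2"),
) -> MGCFAFit:
    """Fit the invariant model directly from per-group summary statistics.

    This is the estimation core behind :func:`fit_invariant_mgcfa`; feeding it
    population (model-implied) thresholds and correlations must return the
    generating parameters to optimizer tolerance.
    """
    # align each group's sample vector with the union threshold structure by
    # masking: cuts unobserved in a group simply drop out of its residuals
    lam0, thr_union, thr0 = _start_values(s1, s2, items)
    thr_sizes = [len(u) for u in thr_union]

    def group_residual_mask(stats: GroupStats) -> np.ndarray:
        keep = []
        for item, union in zip(items, thr_union):
            keep.append(np.isin(union, stats.thr_idx[item]))
        keep.append(np.ones(len(items) * (len(items) - 1) // 2, dtype=bool))
        return np.concatenate(keep)

    mask1, mask2 = group_residual_mask(s1), group_residual_mask(s2)
    svec1, svec2 = _stack_stats(s1, items), _stack_stats(s2, items)

    w1 = np.ones_like(svec1) if weights[0] is None else np.asarray(weights[0], dtype=float)
    w2 = np.ones_like(svec2) if weights[1] is None else np.asarray(weights[1], dtype=float)

    m = len(items)

    def objective(x):
        lam, thr_list, alpha2, psi2 = _unpack(x, m, thr_sizes)
        imp1 = implied_group_stats(lam, thr_list, alpha2, psi2, group=1)[mask1]
        imp2 = implied_group_stats(lam, thr_list, alpha2, psi2, group=2)[mask2]
        r1 = svec1 - imp1
        r2 = svec2 - imp2
        return float(w1 @ r1**2 + w2 @ r2**2)

    x0 = _pack(lam0, thr0, alpha0, 1.0)
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7, "maxfun": 100000},
    )
    if not res.success and "ABNORMAL" not in str(res.message):
        raise ConvergenceError(f"MGCFA optimization failed: {res.message}")

    lam, thr_list, alpha2, psi2 = _unpack(res.x, m, thr_sizes)
    if lam.sum() < 0:  # factor sign is arbitrary; fix sum(lambda) >= 0
        lam, alpha2 = -lam, -alpha2

    heywood = np.abs(lam) >= LAMBDA_BOUND - HEYWOOD_MARGIN
    if heywood.any():
        raise HeywoodError(
            [items[i] for i in np.flatnonzero(heywood)], lam[heywood]
        )

    params = MGCFAParams(
        item_names=items,
        loadings=lam,
        thresholds={
            item: (np.asarray(u), t) for item, u, t in zip(items, thr_union, thr_list)
        },
        alpha2=float(alpha2),
        psi2=float(psi2),
    )
    return MGCFAFit(
        params=params,
        discrepancy=float(res.fun),
        converged=True,
        n_iter=int(res.nit),
        n1=s1.n,
        n2=s2.n,
        estimator=estimator,
        group_levels=group_levels,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def latent_d(fit: MGCFAFit) -> float:
    """Standardized latent mean difference, group 1 minus group 2.

    (alpha1 - alpha2) / sd_pooled with alpha1 = 0 and the classical
    (n-1)-weighted pooled latent SD sqrt(((n1-1) + (n2-1) psi2)/(n1+n2-2)).
    """
    psi2 = fit.params.psi2
    if psi2 <= 0:
        raise ValueError("group-2 latent variance must be positive")
    sd_pool = np.sqrt(((fit.n1 - 1) * 1.0 + (fit.n2 - 1) * psi2) / (fit.n1 + fit.n2 - 2))
    return float(-fit.params.alpha2 / sd_pool)


def mcdonald_omega(fit: MGCFAFit) -> float:
    """McDonald's omega of the scale on the latent-response metric.

    (sum lambda)^2 psi_bar / ((sum lambda)^2 psi_bar + sum theta) with
    psi_bar the sample-size-weighted pooled latent variance; residual
    variances are shared across groups in the raw metric, so theta pools to
    itself.  Computed from the constrained model's estimates.
    """
    p = fit.params
    theta = p.residual_variances
    if np.any(theta <= 0):
        raise HeywoodError(
            [p.item_names[i] for i in np.flatnonzero(theta <= 0)],
            p.loadings[theta <= 0],
        )
    psi_bar = (fit.n1 * 1.0 + fit.n2 * p.psi2) / (fit.n1 + fit.n2)
    common = p.loadings.sum() ** 2 * psi_bar
    return float(common / (common + theta.sum()))
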