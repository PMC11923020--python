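"""Thresholds and polychoric correlations for ordinal items.

Ordinal CFA treats each observed item as a coarsened view of a standard-normal
latent response: the k-th threshold is the normal quantile of the cumulative
proportion through category k, and the polychoric correlation of two items is
the correlation of their latent responses, estimated by maximum likelihood on
the two-way contingency table with the thresholds held fixed at their
univariate estimates (the usual two-step approach).  These per-group summary
statistics are the inputs to the least-squares CFA fitting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

from .synthetic_data import ItemResponseData

__all__ = [
    "ThresholdSet",
    "PolychoricMatrix",
    "PolychoricEstimate",
    "EstimationError",
    "bvn_cdf",
    "estimate_thresholds",
    "polychoric_corr",
    "polychoric_matrix",
]

RHO_BOUND = 0.999
_LOG_FLOOR = 1e-300


class EstimationError(RuntimeError):
    """Threshold or correlation estimation failed for a named item or pair."""


@dataclass(frozen=True)
class ThresholdSet:
    """Ascending cut-points per item on the standard-normal latent scale."""

    thresholds: dict[str, np.ndarray]

    def __getitem__(self, item: str) -> np.ndarray:
        return self.thresholds[item]

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.thresholds)


@dataclass(frozen=True)
class PolychoricEstimate:
    rho: float
    loglik: float
    at_boundary: bool = False


@dataclass(frozen=True)
class PolychoricMatrix:
    """Item-by-item polychoric correlations for one group."""

    items: tuple[str, ...]
    values: np.ndarray
    n: int
    boundary_pairs: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.items), len(self.items)):
            raise ValueError("correlation matrix shape does not match items")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 1.0):
            raise ValueError("polychoric matrix must be symmetric with unit diagonal")


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) via Owen's T function.

    Accurate to ~1e-15 and vectorized over h, k; rho must satisfy |rho| < 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    # keep the h=0 / k=0 and infinite cases off the singular axes of the
    # T-function arguments; the induced error is below 1e-12
    h = np.clip(np.where(np.abs(h) < 1e-12, 1e-12, h), -37.0, 37.0)
    k = np.clip(np.where(np.abs(k) < 1e-12, 1e-12, k), -37.0, 37.0)
    s = np.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * s)
    a2 = (h - rho * k) / (k * s)
    delta = np.where(h * k < 0, 0.5, 0.0)
    return 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2) - delta


def _thresholds_indexed(counts: np.ndarray, item: str = "item") -> tuple[np.ndarray, np.ndarray]:
    """Cut indices and threshold values from category counts.

    Only cuts that separate observed categories are returned (empty leading,
    trailing or interior categories contribute no estimable cut-point); the
    index identifies which model threshold each value corresponds to, so
    groups with different observed category coverage can still be aligned.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts > 0).sum() < 2:
        raise EstimationError(f"{item}: item is constant, thresholds undefined")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    keep = (cum > 0) & (cum < 1)
    # first occurrence only: an empty interior category duplicates the cum value
    keep[1:] &= cum[1:] > cum[:-1]
    idx = np.flatnonzero(keep)
    return idx, ndtri(cum[idx])


def estimate_thresholds(
    categories: np.ndarray, n_categories: int | None = None, item: str = "item"
) -> np.ndarray:
    """Normal-quantile thresholds from one item's category frequencies.

    The k-th threshold is Phi^-1 of the cumulative sample proportion through
    category k; the returned values are strictly increasing.
    """
    cats = np.asarray(categories, dtype=np.int64)
    if cats.size == 0:
        raise EstimationError(f"{item}: no observations")
    if n_categories is None:
        n_categories = int(cats.max()) + 1
    counts = np.bincount(cats, minlength=n_categories)
    return _thresholds_indexed(counts, item=item)[1]


def _cell_probs(rho: float, ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal for all category cells."""
    a = np.concatenate(([-np.inf], ta, [np.inf]))
    b = np.concatenate(([-np.inf], tb, [np.inf]))
    big = 37.0
    a = np.clip(a, -big, big)
    b = np.clip(b, -big, big)
    grid = bvn_cdf(a[:, None], b[None, :], rho)
    # boundary rows/cols: CDF at -inf is 0; at +inf the marginal CDF
    grid[0, :] = 0.0
    grid[:, 0] = 0.0
    grid[-1, :] = ndtr(b)
    grid[:, -1] = ndtr(a)
    grid[-1, -1] = 1.0
    return np.diff(np.diff(grid, axis=0), axis=1)


def _table_loglik(rho: float, table: np.ndarray, ta: np.ndarray, tb: np.ndarray) -> float:
    p = _cell_probs(rho, ta, tb)
    mask = table > 0
    return float(np.sum(table[mask] * np.log(np.maximum(p[mask], _LOG_FLOOR))))


def polychoric_corr(
    table: np.ndarray,
    thresholds_a: np.ndarray,
    thresholds_b: np.ndarray,
    xatol: float = 1e-7,
) -> PolychoricEstimate:
    """Two-step ML polychoric correlation from a contingency table.

    Maximizes the bivariate-normal cell-probability likelihood over
    rho in [-0.999, 0.999] with the thresholds fixed; empty cells contribute
    zero to the log-likelihood.  Estimates landing on the bound (perfect or
    near-perfect association) are returned clamped with ``at_boundary`` set.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise EstimationError("contingency table is empty")
    ta = np.asarray(thresholds_a, dtype=float)
    tb = np.asarray(thresholds_b, dtype=float)
    res = minimize_scalar(
        lambda r: -_table_loglik(r, table, ta, tb),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": xatol},
    )
    if not res.success:
        raise EstimationError(f"polychoric ML failed to converge: {res.message}")
    rho = float(res.x)
    at_boundary = abs(rho) >= RHO_BOUND - 10 * xatol
    if at_boundary:
        rho = float(np.sign(rho) * RHO_BOUND)
    return PolychoricEstimate(rho=rho, loglik=-float(res.fun), at_boundary=at_boundary)


def polychoric_matrix(
    data: ItemResponseData, group
) -> tuple[PolychoricMatrix, ThresholdSet]:
    """All pairwise polychoric correlations and thresholds for one group.

    The matrix is assembled entry-wise and may be non-positive-definite in
    small samples; the CFA fitting stage works on the raw entries and does
    not require positive definiteness.
    """
    if group not in data.group_levels:
        raise ValueError(f"group {group!r} not present (levels: {data.group_levels})")
    items = tuple(data.scale_def.items)
    sub = data.responses.loc[data.group_mask(group), list(items)]
    n_cat = data.scale_def.n_categories
    resp = sub.to_numpy(dtype=np.int64)

    thresholds = {}
    for j, item in enumerate(items):
        thresholds[item] = estimate_thresholds(resp[:, j], n_cat, item=item)

    m = len(items)
    rho = np.eye(m)
    boundary = []
    for i in range(m):
        for j in range(i + 1, m):
            table = np.zeros((n_cat, n_cat))
            np.add.at(table, (resp[:, i], resp[:, j]), 1.0)
            # strip empty categories so table cells align with the thresholds
            rows = table.sum(axis=1) > 0
            cols = table.sum(axis=0) > 0
            try:
                est = polychoric_corr(
                    table[np.ix_(rows, cols)], thresholds[items[i]], thresholds[items[j]]
                )
            except EstimationError as exc:
                raise EstimationError(f"pair ({items[i]}, {items[j]}): {exc}") from exc
            rho[i, j] = rho[j, i] = est.rho
            if est.at_boundary:
                boundary.append((items[i], items[j]))
    return (
        PolychoricMatrix(items=items, values=rho, n=len(sub), boundary_pairs=tuple(boundary)),
        ThresholdSet(thresholds=thresholds),
    )
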