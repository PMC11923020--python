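"""Two-group synthetic questionnaire data with a known true-score structure.

Two generators live here.  ``generate_continuous_ctt`` draws continuous
observed = true + error scores from a classical-test-theory scenario, so the
attenuation of Cohen's d can be checked directly against its closed form.
``generate_ordinal_factor_data`` draws Likert-type item responses from a
unidimensional congeneric factor model: a latent trait per respondent, a
linear latent item response per item, and ordinal categories obtained by
thresholding.  Loadings and thresholds are identical in both groups, i.e. the
data satisfy the scalar-invariance assumption the downstream multigroup CFA
imposes; the only group differences are the latent mean and variance.

Group-difference convention: ``latent_d`` is the standardized latent mean
difference (group 1 minus group 2) over the pooled latent SD, matching the
sign convention of the reported d statistics.  Group 1 is fixed at mean 0 and
variance 1, so the group-2 latent mean is ``-latent_d`` when the group-2
variance is 1, and ``-latent_d * sd_pooled`` otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ctt_attenuation import error_variance

__all__ = [
    "CTTScenario",
    "OrdinalFactorConfig",
    "ScaleDefinition",
    "ItemResponseData",
    "DegenerateItemError",
    "generate_continuous_ctt",
    "generate_ordinal_factor_data",
    "implied_scale_reliability",
    "quintile_thresholds",
    "write_item_csv",
    "read_item_csv",
]


class DegenerateItemError(ValueError):
    """An item shows fewer than two observed categories within a group."""


# ---------------------------------------------------------------------------
# scenario / config types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CTTScenario:
    """True-score model for a continuous observed score.

    delta_mu
        True-score mean difference between the groups (group 1 minus group 2),
        in score units.
    var_tau
        True-score variance, identical in both groups.
    reliability
        Proportion of observed variance that is true-score variance, in (0, 1].
    """

    delta_mu: float
    var_tau: float
    reliability: float

    def __post_init__(self) -> None:
        if self.var_tau <= 0:
            raise ValueError("var_tau must be positive")
        if not 0.0 < self.reliability <= 1.0:
            raise ValueError("reliability must lie in (0, 1]")

    @property
    def var_eps(self) -> float:
        return error_variance(self.reliability, self.var_tau)


def quintile_thresholds(n_categories: int = 5) -> np.ndarray:
    """Thresholds at normal quantiles of equal category probabilities.

    The default Likert emulation: five categories, cut-points at
    Phi^-1(0.2, 0.4, 0.6, 0.8).
    """
    from scipy.stats import norm

    probs = np.arange(1, n_categories) / n_categories
    return norm.ppf(probs)


@dataclass(frozen=True)
class OrdinalFactorConfig:
    """Generating model for one scale of ordinal items in two groups.

    loadings
        Per-item slope of the latent trait on the latent item response.
    thresholds
        Per-item ascending cut-points on the latent item-response scale;
        an item with k cut-points yields k + 1 categories.
    residual_variances
        Per-item unique variance of the latent item response.
    group_sizes
        (n1, n2) respondents per group.
    latent_d
        Standardized latent mean difference, group 1 minus group 2, on the
        group-1 SD scale when ``latent_var_g2`` is 1 and on the pooled latent
        SD scale otherwise (see module docstring).
    latent_var_g2
        Latent trait variance of group 2 (group 1 is fixed at 1).
    """

    loadings: tuple[float, ...]
    thresholds: tuple[tuple[float, ...], ...]
    residual_variances: tuple[float, ...]
    group_sizes: tuple[int, int]
    latent_d: float = 0.0
    latent_var_g2: float = 1.0
    seed: int = 0
    item_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = self.n_items
        if m < 3:
            raise ValueError("at least 3 items are required for identification")
        if len(self.thresholds) != m or len(self.residual_variances) != m:
            raise ValueError("loadings, thresholds and residual_variances must align")
        for t in self.thresholds:
            arr = np.asarray(t, dtype=float)
            if arr.size < 1 or np.any(np.diff(arr) <= 0):
                raise ValueError("thresholds must be strictly increasing per item")
        if any(v <= 0 for v in self.residual_variances):
            raise ValueError("residual_variances must be positive")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("each group needs at least 2 respondents")
        if self.latent_var_g2 <= 0:
            raise ValueError("latent_var_g2 must be positive")
        if min(self.group_sizes) < 20 * m:
            warnings.warn(
                f"group sizes {self.group_sizes} fall below 20 respondents per "
                f"indicator for {m} items; ordinal CFA estimates may be unstable",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_items(self) -> int:
        return len(self.loadings)

    @property
    def names(self) -> tuple[str, ...]:
        if self.item_names is not None:
            return self.item_names
        return tuple(f"item{i + 1}" for i in range(self.n_items))

    @property
    def group2_latent_mean(self) -> float:
        """Group-2 latent mean implied by latent_d (group 1 at 0)."""
        n1, n2 = self.group_sizes
        sd_pool = np.sqrt(
            ((n1 - 1) * 1.0 + (n2 - 1) * self.latent_var_g2) / (n1 + n2 - 2)
        )
        return -self.latent_d * sd_pool

    @classmethod
    def simple(
        cls,
        n_items: int = 6,
        loading: float = 0.7,
        n_categories: int = 5,
        group_sizes: tuple[int, int] = (1000, 1000),
        latent_d: float = 0.0,
        latent_var_g2: float = 1.0,
        seed: int = 0,
    ) -> "OrdinalFactorConfig":
        """Homogeneous scale: equal loadings, quintile thresholds, unit
        latent-response variances (residual variance 1 - loading^2)."""
        thr = tuple(quintile_thresholds(n_categories))
        return cls(
            loadings=(loading,) * n_items,
            thresholds=(thr,) * n_items,
            residual_variances=(1.0 - loading**2,) * n_items,
            group_sizes=group_sizes,
            latent_d=latent_d,
            latent_var_g2=latent_var_g2,
            seed=seed,
        )


@dataclass(frozen=True)
class ScaleDefinition:
    """Item membership, reverse-keying and scoring rule for one scale."""

    items: tuple[str, ...]
    reverse_keyed: tuple[str, ...] = ()
    scoring: str = "sum"
    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.scoring not in ("sum", "mean"):
            raise ValueError("scoring must be 'sum' or 'mean'")
        unknown = set(self.reverse_keyed) - set(self.items)
        if unknown:
            raise ValueError(f"reverse-keyed items not in scale: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "items": list(self.items),
            "reverse_keyed": list(self.reverse_keyed),
            "scoring": self.scoring,
            "n_categories": self.n_categories,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScaleDefinition":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            items=tuple(payload["items"]),
            reverse_keyed=tuple(payload.get("reverse_keyed", ())),
            scoring=payload.get("scoring", "sum"),
            n_categories=int(payload.get("n_categories", 5)),
        )


@dataclass
class ItemResponseData:
    """Complete item responses for two groups of respondents.

    responses holds 0-based integer categories (respondent x item); group is a
    two-level label per respondent.  Construction rejects missing values and
    items that are constant within a group, since neither can be handled by
    the threshold/polychoric stage.
    """

    responses: pd.DataFrame
    group: pd.Series
    scale_def: ScaleDefinition
    config: OrdinalFactorConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.responses.isna().any().any():
            raise ValueError("responses contain missing values; filter first")
        if len(self.group) != len(self.responses):
            raise ValueError("group labels must align with responses")
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {list(levels)}")
        for g in levels:
            sub = self.responses.loc[np.asarray(self.group) == g]
            n_cats = sub.nunique()
            bad = n_cats[n_cats < 2]
            if len(bad):
                raise DegenerateItemError(
                    f"items constant within group {g!r}: {list(bad.index)}"
                )

    @property
    def group_levels(self) -> tuple:
        """Sorted group labels; the first is 'group 1' in all d conventions."""
        return tuple(sorted(pd.unique(self.group)))

    def group_mask(self, level) -> np.ndarray:
        return np.asarray(self.group) == level

    @property
    def group_sizes(self) -> tuple[int, int]:
        g1, g2 = self.group_levels
        return int(self.group_mask(g1).sum()), int(self.group_mask(g2).sum())

    def scored(self) -> pd.Series:
        """Observed scale score: reverse-key, then sum or mean across items."""
        vals = self.responses[list(self.scale_def.items)].to_numpy(dtype=float)
        max_cat = self.scale_def.n_categories - 1
        for j, item in enumerate(self.scale_def.items):
            if item in self.scale_def.reverse_keyed:
                vals[:, j] = max_cat - vals[:, j]
        score = vals.sum(axis=1) if self.scale_def.scoring == "sum" else vals.mean(axis=1)
        return pd.Series(score, index=self.responses.index, name="score")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _group_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Two deterministic sub-streams from one integer seed."""
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def generate_continuous_ctt(
    scenario: CTTScenario, n_per_group: int, seed: int = 0
) -> pd.DataFrame:
    """Continuous true and observed scores for two groups.

    Group 1 true scores are Normal(delta_mu, var_tau), group 2 Normal(0,
    var_tau); the observed score adds independent Normal(0, var_eps) error.
    Both columns are returned so attenuation can be measured against the true
    scores directly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    rng1, rng2 = _group_streams(seed)
    sd_tau = np.sqrt(scenario.var_tau)
    sd_eps = np.sqrt(scenario.var_eps)
    frames = []
    for label, mu, rng in (("g1", scenario.delta_mu, rng1), ("g2", 0.0, rng2)):
        tau = rng.normal(mu, sd_tau, n_per_group)
        obs = tau + (rng.normal(0.0, sd_eps, n_per_group) if sd_eps > 0 else 0.0)
        frames.append(pd.DataFrame({"group": label, "true": tau, "observed": obs}))
    return pd.concat(frames, ignore_index=True)


def generate_ordinal_factor_data(config: OrdinalFactorConfig) -> ItemResponseData:
    """Ordinal item responses from the congeneric factor model in ``config``.

    For each respondent the latent trait is drawn from the group's normal
    distribution, each latent item response is loading * trait plus normal
    unique error, and the observed category is the number of thresholds below
    the latent response.  Raises :class:`DegenerateItemError` if any item is
    constant within a group (downstream estimation would be impossible).
    """
    n1, n2 = config.group_sizes
    rng1, rng2 = _group_streams(config.seed)
    lam = np.asarray(config.loadings, dtype=float)
    sd_res = np.sqrt(np.asarray(config.residual_variances, dtype=float))
    alpha2 = config.group2_latent_mean

    blocks, labels = [], []
    specs = (
        ("g1", 0.0, 1.0, n1, rng1),
        ("g2", alpha2, config.latent_var_g2, n2, rng2),
    )
    for label, mu, var, n, rng in specs:
        eta = rng.normal(mu, np.sqrt(var), n)
        ystar = eta[:, None] * lam[None, :] + rng.normal(0.0, 1.0, (n, config.n_items)) * sd_res[None, :]
        cats = np.empty((n, config.n_items), dtype=np.int64)
        for j, thr in enumerate(config.thresholds):
            cats[:, j] = np.searchsorted(np.asarray(thr, dtype=float), ystar[:, j], side="left")
        blocks.append(cats)
        labels.extend([label] * n)

    responses = pd.DataFrame(np.vstack(blocks), columns=list(config.names))
    n_categories = max(len(t) for t in config.thresholds) + 1
    scale_def = ScaleDefinition(items=config.names, scoring="sum", n_categories=n_categories)
    return ItemResponseData(
        responses=responses,
        group=pd.Series(labels, name="group"),
        scale_def=scale_def,
        config=config,
    )


def implied_scale_reliability(config: OrdinalFactorConfig) -> float:
    """McDonald's omega of the latent item responses implied by ``config``.

    omega = (sum lambda)^2 psi_pooled / ((sum lambda)^2 psi_pooled + sum theta)
    with psi_pooled the sample-size-weighted pooled latent variance.  This is
    the reliability of the (continuous) latent composite; thresholding into
    few categories loses a little additional information, so the ordinal
    sum score's reliability sits slightly below this value.
    """
    lam = np.asarray(config.loadings, dtype=float)
    theta = np.asarray(config.residual_variances, dtype=float)
    n1, n2 = config.group_sizes
    psi_pool = (n1 * 1.0 + n2 * config.latent_var_g2) / (n1 + n2)
    common = lam.sum() ** 2 * psi_pool
    denom = common + theta.sum()
    if denom == 0:
        return 0.0
    return float(common / denom)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def write_item_csv(data: ItemResponseData, path: str | Path) -> None:
    """Item categories plus a trailing 'group' column, plain CSV."""
    out = data.responses.copy()
    out["group"] = np.asarray(data.group)
    out.to_csv(path, index=False)


def read_item_csv(
    path: str | Path,
    scale_def: ScaleDefinition,
    group_col: str = "group",
) -> ItemResponseData:
    raw = pd.read_csv(path)
    if group_col not in raw.columns:
        raise ValueError(f"column {group_col!r} not found in {path}")
    items = [c for c in raw.columns if c != group_col]
    missing = set(scale_def.items) - set(items)
    if missing:
        raise ValueError(f"scale items absent from CSV: {sorted(missing)}")
    return ItemResponseData(
        responses=raw[items].astype(np.int64),
        group=raw[group_col],
        scale_def=scale_def,
    )
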