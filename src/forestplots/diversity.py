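"""Taxonomic diversity indices and additive hierarchical partitioning.

Richness, Shannon diversity (natural log) and Pielou evenness at the
subplot/plot level, and the additive decomposition of total (gamma)
richness into within-level means (alpha_k) and between-level
differences (beta_k) over a nested sampling hierarchy, satisfying

    gamma = alpha_1 + beta_1 + ... + beta_L   exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datagen import AbundanceMatrix

__all__ = [
    "richness",
    "shannon",
    "evenness",
    "PlotDiversity",
    "plot_diversity",
    "DiversityPartition",
    "additive_partition",
    "partition_from_level_means",
]


def richness(abundances: Sequence[float] | np.ndarray) -> int:
    """Number of taxa with strictly positive abundance."""
    x = np.asarray(abundances, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("abundances must be finite")
    if (x < 0).any():
        raise ValueError("abundances must be >= 0")
    return int(np.count_nonzero(x > 0))


def shannon(abundances: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over positive entries."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be >= 0")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("Shannon diversity is undefined for an all-zero vector")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def evenness(h: float, s: int) -> float:
    """Pielou evenness J = H / ln S; defined as 0 for S = 1."""
    if s < 1:
        raise ValueError("richness must be >= 1")
    if h < 0:
        raise ValueError("H must be >= 0")
    if s == 1:
        if h > 1e-9:
            raise ValueError("H > 0 is inconsistent with S = 1")
        return 0.0
    hmax = np.log(s)
    if h > hmax + 1e-9:
        raise ValueError(f"H = {h} exceeds ln S = {hmax}")
    return float(min(h / hmax, 1.0))


@dataclass(frozen=True)
class PlotDiversity:
    """Per-plot diversity: alpha/beta/gamma over subplots, H and E pooled."""

    plot_id: str
    alpha: float  # mean subplot richness
    gamma: float  # richness of the pooled subplot abundances
    beta: float  # gamma - alpha
    shannon: float
    evenness: float


def plot_diversity(
    cover: AbundanceMatrix, design: pd.DataFrame
) -> list[PlotDiversity]:
    """Alpha (mean subplot richness), gamma (pooled richness), beta,
    Shannon and evenness per plot, from a subplot-level cover matrix."""
    if cover.level != "subplot":
        raise ValueError("plot_diversity expects a subplot-level matrix")
    plot_of = design.set_index("subplot_id")["plot_id"]
    out: list[PlotDiversity] = []
    for plot_id in design["plot_id"].drop_duplicates():
        sub = cover.df.loc[plot_of.reindex(cover.df.index) == plot_id]
        pooled = sub.sum(axis=0).to_numpy()
        g = richness(pooled)
        if g == 0:
            warnings.warn(f"plot {plot_id} has no recorded taxa", stacklevel=2)
            out.append(PlotDiversity(plot_id, 0.0, 0.0, 0.0, 0.0, 0.0))
            continue
        a = float(np.mean([richness(r) for r in sub.to_numpy()]))
        h = shannon(pooled)
        out.append(PlotDiversity(plot_id, a, float(g), float(g) - a, h, evenness(h, g)))
    return out


@dataclass(frozen=True)
class DiversityPartition:
    """Additive partition: alpha means per level, successive betas, gamma.

    ``percent`` expresses alpha_1 and each beta as a share of gamma (the
    components that sum to 100%); ``alpha_percent`` gives every alpha
    level as a share of gamma.
    """

    levels: tuple[str, ...]
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    gamma: float

    def __post_init__(self) -> None:
        L = len(self.levels)
        if len(self.alpha) != L or len(self.beta) != L:
            raise ValueError("alpha/beta must have one entry per level")
        resid = self.alpha[0] + sum(self.beta) - self.gamma
        if abs(resid) > 1e-9:
            raise ValueError(f"partition identity violated (residual {resid})")

    @property
    def components(self) -> dict[str, float]:
        d = {"alpha_1": self.alpha[0]}
        for k, b in enumerate(self.beta, start=1):
            d[f"beta_{k}"] = b
        return d

    @property
    def percent(self) -> dict[str, float]:
        return {k: 100.0 * v / self.gamma for k, v in self.components.items()}

    @property
    def alpha_percent(self) -> tuple[float, ...]:
        return tuple(100.0 * a / self.gamma for a in self.alpha)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": f"alpha_{k + 1}", "value": a, "percent": 100 * a / self.gamma}
            for k, a in enumerate(self.alpha)
        ]
        rows += [
            {"component": f"beta_{k + 1}", "value": b, "percent": 100 * b / self.gamma}
            for k, b in enumerate(self.beta)
        ]
        rows.append({"component": "gamma", "value": self.gamma, "percent": 100.0})
        return pd.DataFrame(rows)


def partition_from_level_means(
    alpha_means: Sequence[float], gamma: float, levels: Sequence[str] | None = None
) -> DiversityPartition:
    """Partition from already-computed level means.

    beta_k = alpha_{k+1} - alpha_k for k < L and beta_L = gamma -
    alpha_L, so the additive identity holds by construction.
    """
    alpha = tuple(float(a) for a in alpha_means)
    if any(a < 0 for a in alpha):
        raise ValueError("alpha means must be >= 0")
    beta = tuple(
        (alpha[k + 1] if k + 1 < len(alpha) else float(gamma)) - alpha[k]
        for k in range(len(alpha))
    )
    if levels is None:
        levels = tuple(f"level_{k + 1}" for k in range(len(alpha)))
    return DiversityPartition(tuple(levels), alpha, beta, float(gamma))


def additive_partition(
    cover: AbundanceMatrix,
    hierarchy: pd.DataFrame,
    levels: Sequence[str],
    weights: str = "unweighted",
) -> DiversityPartition:
    """Additive richness partition over a nested hierarchy.

    Parameters
    ----------
    cover
        Unit x taxon abundances; the rows are the base sampling units.
    hierarchy
        Table with one row per base unit (indexed or keyed by the
        cover's unit ids in its first column) and one grouping column
        per level, ordered fine -> coarse.
    levels
        Names of the grouping columns, ordered fine -> coarse.
    weights
        ``"unweighted"`` (mean over groups; the design is balanced) or
        ``"size"`` (groups weighted by their number of base units).
    """
    if weights not in ("unweighted", "size"):
        raise ValueError("weights must be 'unweighted' or 'size'")
    h = hierarchy.copy()
    if h.index.name is None and h.columns[0] not in levels:
        h = h.set_index(h.columns[0])
    h = h.loc[cover.units, list(levels)]

    # nestedness: each level-k group must map to exactly one parent
    for k in range(len(levels) - 1):
        child, parent = levels[k], levels[k + 1]
        n_parents = h.groupby(child)[parent].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            raise ValueError(
                f"hierarchy is not nested: {child} group(s) "
                f"{list(bad.index)} map to multiple {parent} groups"
            )

    X = cover.df
    alphas: list[float] = []
    for level in levels:
        pooled = X.groupby(h[level]).sum()
        rich = (pooled.to_numpy() > 0).sum(axis=1).astype(float)
        if weights == "unweighted":
            alphas.append(float(rich.mean()))
        else:
            sizes = h.groupby(level).size().reindex(pooled.index).to_numpy()
            alphas.append(float(np.average(rich, weights=sizes)))
    gamma = float(richness(X.sum(axis=0).to_numpy()))
    return partition_from_level_means(alphas, gamma, levels=levels)
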