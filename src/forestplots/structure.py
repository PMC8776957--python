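"""Dendrometric structural diversity per plot.

Density, branch-wise basal area (BA = DBH^2 * pi / 4 summed over
branches), BA-share Shannon/evenness, and height summaries.  The
survey inclusion rule — a tree counts only if its largest branch DBH
is at least 2.5 cm — is applied here, before any statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datagen import SurveyDataset, TreeRecord
from .diversity import evenness, shannon

__all__ = [
    "DBH_THRESHOLD_CM",
    "tree_basal_area",
    "stand_density",
    "StandStructure",
    "stand_structure",
    "structure_report",
]

DBH_THRESHOLD_CM = 2.5


def retained(tree: TreeRecord, threshold_cm: float = DBH_THRESHOLD_CM) -> bool:
    """Inclusion rule: the largest branch diameter must reach the threshold."""
    return max(tree.branch_dbh_cm) >= threshold_cm


def tree_basal_area(branch_dbh_cm: Sequence[float]) -> float:
    """Cross-sectional area in m2, summed over branches: sum (d/100)^2 pi/4."""
    if len(branch_dbh_cm) == 0:
        raise ValueError("need at least one branch diameter")
    if any(d <= 0 for d in branch_dbh_cm):
        raise ValueError("branch diameters must be > 0")
    return float(sum((d / 100.0) ** 2 * math.pi / 4.0 for d in branch_dbh_cm))


def stand_density(n_trees: int, plot_area_m2: float) -> float:
    """Trees per hectare: count * 10000 / plot area."""
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be > 0")
    return n_trees * 10_000.0 / plot_area_m2


@dataclass(frozen=True)
class StandStructure:
    plot_id: str
    n_trees: int
    density_per_ha: float
    ba_m2: float  # per-plot basal area
    ba_m2_per_ha: float
    ba_per_taxon: dict[str, float]  # m2 per plot
    ba_gamma: int  # taxa contributing BA
    ba_shannon: float
    ba_evenness: float
    height_mean_m: float
    height_sd_m: float
    height_max_m: float


def stand_structure(
    trees: Sequence[TreeRecord], plot_area_m2: float, plot_id: str | None = None
) -> StandStructure:
    """Structural summary of one plot's retained trees."""
    plot_ids = {t.plot_id for t in trees}
    if len(plot_ids) > 1:
        raise ValueError("all trees must share one plot_id")
    if plot_id is None:
        plot_id = plot_ids.pop() if plot_ids else "<empty>"

    kept = [t for t in trees if retained(t)]
    if not kept:
        warnings.warn(f"plot {plot_id}: no trees above the DBH threshold", stacklevel=2)
        return StandStructure(plot_id, 0, 0.0, 0.0, 0.0, {}, 0, 0.0, 0.0, 0.0, 0.0, 0.0)

    ba_per_taxon: dict[str, float] = {}
    for t in kept:
        ba_per_taxon[t.taxon_id] = ba_per_taxon.get(t.taxon_id, 0.0) + tree_basal_area(
            t.branch_dbh_cm
        )
    ba = sum(ba_per_taxon.values())
    shares = np.array(list(ba_per_taxon.values()))
    gamma = int((shares > 0).sum())
    h = shannon(shares) if gamma >= 1 else 0.0
    e = evenness(h, gamma) if gamma >= 1 else 0.0
    heights = np.array([t.height_m for t in kept])
    return StandStructure(
        plot_id=plot_id,
        n_trees=len(kept),
        density_per_ha=stand_density(len(kept), plot_area_m2),
        ba_m2=float(ba),
        ba_m2_per_ha=float(ba * 10_000.0 / plot_area_m2),
        ba_per_taxon=ba_per_taxon,
        ba_gamma=gamma,
        ba_shannon=float(h),
        ba_evenness=float(e),
        height_mean_m=float(heights.mean()),
        height_sd_m=float(heights.std(ddof=1)) if len(kept) > 1 else 0.0,
        height_max_m=float(heights.max()),
    )


def structure_report(dataset: SurveyDataset, plot_area_m2: float | None = None) -> pd.DataFrame:
    """Per-plot structural summary table for a whole survey."""
    if plot_area_m2 is None:
        plot_area_m2 = dataset.config.plot_area_m2 if dataset.config else 100.0
    by_plot: dict[str, list[TreeRecord]] = {}
    for t in dataset.trees:
        by_plot.setdefault(t.plot_id, []).append(t)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, d in dataset.plot_design.iterrows():
            s = stand_structure(by_plot.get(d["plot_id"], []), plot_area_m2, d["plot_id"])
            rows.append(
                {
                    "plot_id": s.plot_id,
                    "island": d["island"],
                    "forest_type": d["forest_type"],
                    "density_per_ha": s.density_per_ha,
                    "ba_m2": s.ba_m2,
                    "ba_m2_per_ha": s.ba_m2_per_ha,
                    "ba_gamma": s.ba_gamma,
                    "ba_shannon": s.ba_shannon,
                    "ba_evenness": s.ba_evenness,
                    "height_mean_m": s.height_mean_m,
                    "height_sd_m": s.height_sd_m,
                    "height_max_m": s.height_max_m,
                }
            )
    return pd.DataFrame(rows)
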