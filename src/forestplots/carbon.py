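"""Carbon-stock accounting in three pools, all reported in Mg C ha-1.

* Standing trees: above-ground biomass from an allometric-equation
  registry, below-ground biomass as root:shoot ratio x AGB, and
  leaf-type carbon fractions (0.48 broadleaf, 0.51 conifer).
* Leaf litter: dry mass (g m-2) x carbon concentration (g C kg-1).
* Soil: organic matter x 0.58 (Van Bemmelen) x bulk density x sampled
  depth, scaled to one hectare.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datagen import LitterSample, SoilSample, SurveyDataset, Taxon, TreeRecord
from .structure import retained

__all__ = [
    "AllometricEquation",
    "EquationRegistry",
    "CarbonParameters",
    "default_registry",
    "equivalent_diameter",
    "tree_agb",
    "tree_total_carbon",
    "plot_tree_carbon",
    "litter_carbon",
    "soil_carbon",
    "carbon_report",
]

FORMS = ("power_d", "power_d2h", "loglinear_dh", "linear_ba", "linear")


@dataclass(frozen=True)
class AllometricEquation:
    """One registry entry mapping a taxon to an AGB formula (kg dry mass).

    Forms and their coefficients:

    ``power_d``       a * D^b                     (D in cm)
    ``power_d2h``     a * (D^2 H)^b               (H in m)
    ``loglinear_dh``  exp(a + b ln D + c ln H)
    ``linear_ba``     a + b * BA                  (per-tree BA in m2)
    ``linear``        a + sum coef_X * X over declared predictors
                      (X in {D, H, BA, NB})
    """

    taxon_id: str  # or "generic"
    form: str
    coefficients: Mapping[str, float]
    predictors: tuple[str, ...] = ("D",)
    source: str = ""

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")

    def evaluate(self, predictors: Mapping[str, float]) -> float:
        c = self.coefficients
        missing = [p for p in self.predictors if p not in predictors]
        if missing:
            raise KeyError(f"missing predictor(s) {missing} for form {self.form!r}")
        D = predictors.get("D")
        H = predictors.get("H")
        BA = predictors.get("BA")
        if self.form == "power_d":
            return c["a"] * D ** c["b"]
        if self.form == "power_d2h":
            return c["a"] * (D**2 * H) ** c["b"]
        if self.form == "loglinear_dh":
            return math.exp(c["a"] + c["b"] * math.log(D) + c["c"] * math.log(H))
        if self.form == "linear_ba":
            return c["a"] + c["b"] * BA
        # general linear over declared predictors
        return c.get("a", 0.0) + sum(
            c[f"coef_{p}"] * predictors[p] for p in self.predictors
        )


class EquationRegistry:
    """Taxon -> allometric equation, with a mandatory generic fallback."""

    def __init__(self, equations: Sequence[AllometricEquation]) -> None:
        self._by_taxon = {eq.taxon_id: eq for eq in equations}
        if "generic" not in self._by_taxon:
            raise ValueError("registry must include a 'generic' fallback equation")

    def resolve(self, taxon_id: str) -> tuple[AllometricEquation, bool]:
        """The equation for a taxon and whether the generic fallback was used."""
        if taxon_id in self._by_taxon:
            return self._by_taxon[taxon_id], False
        return self._by_taxon["generic"], True

    @classmethod
    def from_yaml(cls, path) -> "EquationRegistry":
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        return cls(
            [
                AllometricEquation(
                    taxon_id=e["taxon_id"],
                    form=e["form"],
                    coefficients=e["coefficients"],
                    predictors=tuple(e.get("predictors", ("D",))),
                    source=e.get("source", ""),
                )
                for e in entries
            ]
        )


def default_registry() -> EquationRegistry:
    """The packaged default registry (synthetic literature-style forms)."""
    with resources.as_file(
        resources.files("forestplots.data") / "default_equations.yml"
    ) as p:
        return EquationRegistry.from_yaml(p)


@dataclass(frozen=True)
class CarbonParameters:
    """Biomass-to-carbon conversion constants.

    ``root_shoot_ratio`` ships as configuration (the IPCC 2006
    Guidelines, Vol. 4 Table 4.4, list root:shoot ratios by climate
    zone; 0.25 is a typical temperate-oceanic value).  Carbon fractions
    follow the IPCC defaults of 48% for broadleaves and 51% for
    conifers; by default they apply to total biomass (AGB + BGB), with
    ``fraction_applies_to="agb"`` available for sensitivity runs.
    """

    root_shoot_ratio: float = 0.25
    carbon_fraction_broadleaf: float = 0.48
    carbon_fraction_conifer: float = 0.51
    van_bemmelen: float = 0.58
    fraction_applies_to: str = "total"  # "total" (AGB+BGB) or "agb"

    def __post_init__(self) -> None:
        if not 0 <= self.root_shoot_ratio < 1.5:
            raise ValueError("root_shoot_ratio must be in [0, 1.5)")
        for name in (
            "carbon_fraction_broadleaf",
            "carbon_fraction_conifer",
            "van_bemmelen",
        ):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.fraction_applies_to not in ("total", "agb"):
            raise ValueError("fraction_applies_to must be 'total' or 'agb'")

    def fraction(self, leaf_type: str) -> float:
        if leaf_type == "broadleaf":
            return self.carbon_fraction_broadleaf
        if leaf_type == "conifer":
            return self.carbon_fraction_conifer
        raise ValueError(f"unknown leaf_type {leaf_type!r}")


def equivalent_diameter(branch_dbh_cm: Sequence[float]) -> float:
    """Quadratic-mean diameter sqrt(sum d_i^2): preserves total basal area."""
    return float(math.sqrt(sum(d**2 for d in branch_dbh_cm)))


def tree_agb(
    tree: TreeRecord, registry: EquationRegistry
) -> tuple[float, bool]:
    """Above-ground biomass (kg dry mass) and a generic-fallback flag."""
    from .structure import tree_basal_area

    eq, fallback = registry.resolve(tree.taxon_id)
    preds = {
        "D": equivalent_diameter(tree.branch_dbh_cm),
        "H": tree.height_m,
        "BA": tree_basal_area(tree.branch_dbh_cm),
        "NB": float(len(tree.branch_dbh_cm)),
    }
    agb = eq.evaluate(preds)
    if agb < 0:
        warnings.warn(
            f"tree {tree.tree_id}: negative AGB prediction clamped to 0",
            stacklevel=2,
        )
        agb = 0.0
    return float(agb), fallback


def tree_total_carbon(agb_kg: float, leaf_type: str, params: CarbonParameters) -> float:
    """kg C per tree: fraction(leaf type) x (AGB + root:shoot x AGB)."""
    if agb_kg < 0:
        raise ValueError("AGB must be >= 0")
    bgb = params.root_shoot_ratio * agb_kg
    base = agb_kg + bgb if params.fraction_applies_to == "total" else agb_kg
    return params.fraction(leaf_type) * base


def plot_tree_carbon(
    trees: Sequence[TreeRecord],
    taxa: Mapping[str, Taxon],
    registry: EquationRegistry,
    params: CarbonParameters,
    plot_area_m2: float,
) -> tuple[float, dict[str, float]]:
    """Tree carbon stock (Mg C ha-1) and its per-taxon breakdown.

    Only trees passing the DBH inclusion rule contribute.
    """
    per_taxon: dict[str, float] = {}
    for t in trees:
        if not retained(t):
            continue
        agb, _ = tree_agb(t, registry)
        kg_c = tree_total_carbon(agb, taxa[t.taxon_id].leaf_type, params)
        per_taxon[t.taxon_id] = per_taxon.get(t.taxon_id, 0.0) + kg_c
    scale = 1e-3 * 10_000.0 / plot_area_m2  # kg -> Mg, plot -> ha
    per_taxon = {k: v * scale for k, v in per_taxon.items()}
    return float(sum(per_taxon.values())), per_taxon


def litter_carbon(sample: LitterSample) -> float:
    """Mg C ha-1 from dry mass (g m-2) and C concentration (g C kg-1).

    g m-2 x g C kg-1 x 1e-3 = g C m-2; x 1e4 m2 ha-1 x 1e-6 Mg g-1.
    """
    return sample.dry_mass_g_per_m2 * sample.carbon_conc_gC_per_kg * 1e-3 * 1e-2


def soil_carbon(sample: SoilSample, params: CarbonParameters | None = None) -> float:
    """Mg C ha-1: OM (g kg-1) x Van Bemmelen x BD (kg m-3) x depth (m),
    scaled by 1e4 m2 ha-1 and kg -> Mg."""
    params = params or CarbonParameters()
    om_frac = sample.organic_matter_g_per_kg * 1e-3  # kg OM / kg soil
    c_per_m2 = om_frac * params.van_bemmelen * sample.bulk_density_kg_per_m3 * sample.depth_m
    return c_per_m2 * 1e4 * 1e-3


@dataclass(frozen=True)
class CarbonStockReport:
    per_plot: pd.DataFrame  # plot_id, island, forest_type, c_trees, c_litter, c_soil
    per_taxon: pd.DataFrame  # plot_id, taxon_id, c_trees_Mg_ha
    summary: pd.DataFrame  # island x forest_type cell means and standard errors


def carbon_report(
    dataset: SurveyDataset,
    registry: EquationRegistry | None = None,
    params: CarbonParameters | None = None,
) -> CarbonStockReport:
    """Per-plot carbon stocks in all three pools plus cell summaries.

    Plots without a litter or soil sample get missing values for that
    pool, never silent zeros.
    """
    registry = registry or default_registry()
    params = params or CarbonParameters()
    area = dataset.config.plot_area_m2 if dataset.config else 100.0
    taxa = {t.taxon_id: t for t in dataset.taxa}

    trees_by_plot: dict[str, list[TreeRecord]] = {}
    for t in dataset.trees:
        trees_by_plot.setdefault(t.plot_id, []).append(t)
    litter_by_plot = {s.plot_id: s for s in dataset.litter}
    soil_by_plot = {s.plot_id: s for s in dataset.soil}

    rows, taxon_rows = [], []
    for _, d in dataset.plot_design.iterrows():
        pid = d["plot_id"]
        c_trees, breakdown = plot_tree_carbon(
            trees_by_plot.get(pid, []), taxa, registry, params, area
        )
        for tid, v in breakdown.items():
            taxon_rows.append({"plot_id": pid, "taxon_id": tid, "c_trees_Mg_ha": v})
        lit = litter_by_plot.get(pid)
        so = soil_by_plot.get(pid)
        rows.append(
            {
                "plot_id": pid,
                "island": d["island"],
                "forest_type": d["forest_type"],
                "c_trees_Mg_ha": c_trees,
                "c_litter_Mg_ha": litter_carbon(lit) if lit else np.nan,
                "c_soil_Mg_ha": soil_carbon(so, params) if so else np.nan,
            }
        )
    per_plot = pd.DataFrame(rows)

    def se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(x.count())) if x.count() > 1 else np.nan

    summary = (
        per_plot.groupby(["island", "forest_type"])[
            ["c_trees_Mg_ha", "c_litter_Mg_ha", "c_soil_Mg_ha"]
        ]
        .agg(["mean", se])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in summary.columns
    ]
    per_taxon = pd.DataFrame(taxon_rows, columns=["plot_id", "taxon_id", "c_trees_Mg_ha"])
    return CarbonStockReport(per_plot, per_taxon, summary)
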