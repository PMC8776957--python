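"""Synthetic nested forest-survey generator and shared domain types.

The generator emulates a stratified vegetation survey across three
islands x three forest types (natural forest ``NF``, exotic woodland
``EW``, production forest ``PF``), with 10 plots of 100 m2 per
island x type cell, each split into four 5 x 5 m subplots.  It emits

* a subplot x taxon percent-cover matrix with forest-type-dominant
  abundance structure (a single conifer dominant for PF, one exotic
  broadleaf dominant for EW, several endemic dominants for NF),
* per-tree dendrometric records (branch-wise DBH, height),
* per-plot leaf-litter samples (dry mass, carbon concentration), and
* per-plot soil samples (bulk density, organic matter, depth).

All randomness flows from a single integer seed through named
sub-streams, so adding one component never shifts another's draws and
equal configurations yield bit-identical datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "Taxon",
    "TreeRecord",
    "LitterSample",
    "SoilSample",
    "AbundanceMatrix",
    "SurveyConfig",
    "SurveyDataset",
    "generate_species_pool",
    "generate_survey",
]

STATUSES = ("endemic", "native", "exotic")
GROWTH_FORMS = ("tree", "shrub", "herb", "fern")
LEAF_TYPES = ("broadleaf", "conifer")


class ConfigError(ValueError):
    """Raised when a survey configuration violates an invariant."""


@dataclass(frozen=True)
class Taxon:
    """A vascular-plant taxon in the regional species pool.

    ``affinity`` maps each forest type to a relative occurrence weight
    in [0, 1]; ``leaf_type`` drives the broadleaf/conifer carbon
    fraction downstream.
    """

    taxon_id: str
    name: str
    status: str
    growth_form: str
    leaf_type: str
    affinity: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth_form {self.growth_form!r}")
        if self.leaf_type not in LEAF_TYPES:
            raise ValueError(f"unknown leaf_type {self.leaf_type!r}")
        for ft, w in self.affinity.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"affinity[{ft!r}] must be finite and >= 0")


@dataclass(frozen=True)
class TreeRecord:
    """One measured tree/shrub: branch-wise DBH (cm) and total height (m).

    Trees branching at or below breast height carry one diameter per
    branch.  The survey inclusion rule (largest branch DBH >= 2.5 cm)
    is applied by the structural and carbon modules, not here.
    """

    tree_id: str
    plot_id: str
    taxon_id: str
    branch_dbh_cm: tuple[float, ...]
    height_m: float

    def __post_init__(self) -> None:
        if len(self.branch_dbh_cm) < 1:
            raise ValueError("a tree needs at least one branch diameter")
        if any(d <= 0 for d in self.branch_dbh_cm):
            raise ValueError("branch diameters must be > 0")
        if self.height_m <= 0:
            raise ValueError("height must be > 0")


@dataclass(frozen=True)
class LitterSample:
    """Leaf-litter sample: dry mass (g m-2) and C concentration (g C kg-1)."""

    plot_id: str
    dry_mass_g_per_m2: float
    carbon_conc_gC_per_kg: float

    def __post_init__(self) -> None:
        if self.dry_mass_g_per_m2 < 0:
            raise ValueError("dry mass must be >= 0")
        if not 0 <= self.carbon_conc_gC_per_kg <= 1000:
            raise ValueError("carbon concentration must be in [0, 1000] g C kg-1")


@dataclass(frozen=True)
class SoilSample:
    """Topsoil core: bulk density (kg m-3), organic matter (g kg-1), depth (m)."""

    plot_id: str
    bulk_density_kg_per_m3: float
    organic_matter_g_per_kg: float
    depth_m: float
    ph: float | None = None
    nutrients: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.bulk_density_kg_per_m3 <= 0:
            raise ValueError("bulk density must be > 0")
        if not 0 <= self.organic_matter_g_per_kg <= 1000:
            raise ValueError("organic matter must be in [0, 1000] g kg-1")
        if not 0 < self.depth_m <= 0.30:
            raise ValueError("depth must be in (0, 0.30] m")


class AbundanceMatrix:
    """Sampling-unit x taxon abundance/cover table.

    A thin wrapper over a :class:`pandas.DataFrame` (rows = units in
    design order, columns = taxa) carrying the sampling level
    (``"subplot"`` or ``"plot"``).
    """

    def __init__(self, values: pd.DataFrame, level: str) -> None:
        if level not in ("subplot", "plot"):
            raise ValueError(f"unknown level {level!r}")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate unit or taxon ids")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("abundances must be finite and >= 0")
        self.df = values
        self.level = level

    @property
    def units(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def to_plot_level(self, design: pd.DataFrame) -> "AbundanceMatrix":
        """Sum subplot covers within plots, preserving design order."""
        if self.level == "plot":
            return self
        plot_of = design.set_index("subplot_id")["plot_id"]
        pooled = self.df.groupby(plot_of.reindex(self.df.index)).sum()
        order = design["plot_id"].drop_duplicates().tolist()
        return AbundanceMatrix(pooled.loc[order], level="plot")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AbundanceMatrix)
            and self.level == other.level
            and self.df.equals(other.df)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"AbundanceMatrix({self.df.shape[0]} {self.level}s x {self.df.shape[1]} taxa)"


# --- configuration -------------------------------------------------------

_DEF_ISLANDS = ("Pico", "SaoMiguel", "Terceira")
_DEF_TYPES = ("NF", "EW", "PF")

# Geometric rank-abundance ratio per forest type: smaller = steeper
# dominance (PF is close to a monoculture, NF is the most even).
_DEF_DOMINANCE = {"NF": 0.85, "EW": 0.60, "PF": 0.20}

# Community "openness" to off-home taxa; scales expected richness so
# NF plots are the richest and PF plots the poorest.
_TYPE_OPENNESS = {"NF": 1.2, "EW": 0.7, "PF": 0.3}

_DEF_TREE_DENSITY = {"NF": 3300.0, "EW": 4400.0, "PF": 2100.0}
# (mu, sigma) of the log of DBH in cm, truncated below at 2.5 cm.
_DEF_DBH_LOGNORMAL = {
    "NF": (np.log(7.0), 0.50),
    "EW": (np.log(10.0), 0.50),
    "PF": (np.log(18.0), 0.35),
}
# (mean, sd) of height in m: montane NF stands are short, PF tallest.
_DEF_HEIGHT = {"NF": (4.8, 1.5), "EW": (8.8, 2.0), "PF": (22.0, 4.0)}
# Mean branches beyond the first (Poisson): NF trees are often
# multi-stemmed, planted PF conifers are single-stemmed.
_DEF_EXTRA_BRANCHES = {"NF": 0.8, "EW": 0.2, "PF": 0.0}

# dry mass g m-2 (mean, sd) and carbon conc g C kg-1 (mean, sd):
# conifer litter accumulates, so PF carries the largest stock.
_DEF_LITTER = {
    "NF": {"dry_mass": (400.0, 80.0), "carbon_conc": (360.0, 30.0)},
    "EW": {"dry_mass": (530.0, 110.0), "carbon_conc": (350.0, 30.0)},
    "PF": {"dry_mass": (900.0, 180.0), "carbon_conc": (400.0, 25.0)},
}

# Soil differs mainly by island: young basaltic soils have low bulk
# density and store less carbon than the older islands' andosols.
_DEF_SOIL = {
    "Pico": {"bulk_density": (500.0, 60.0), "organic_matter": (120.0, 20.0)},
    "SaoMiguel": {"bulk_density": (950.0, 90.0), "organic_matter": (160.0, 25.0)},
    "Terceira": {"bulk_density": (1000.0, 90.0), "organic_matter": (180.0, 25.0)},
}


@dataclass(frozen=True)
class SurveyConfig:
    """Parameters of the synthetic survey.

    Defaults reproduce the reference design: 3 islands x 3 forest types
    x 10 plots x 4 subplots of 25 m2, a 108-taxon species pool, and
    forest type as the main compositional driver (``type_effect`` >
    ``island_effect``).  Setting both effects to zero makes group
    labels exchangeable (the null mode used for permutation-test
    calibration).
    """

    islands: tuple[str, ...] = _DEF_ISLANDS
    forest_types: tuple[str, ...] = _DEF_TYPES
    plots_per_cell: int = 10
    subplots_per_plot: int = 4
    subplot_area_m2: float = 25.0
    plot_area_m2: float = 100.0
    species_pool_size: int = 108
    dominance: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_DOMINANCE))
    type_effect: float = 1.0
    island_effect: float = 0.15
    tree_density_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_TREE_DENSITY)
    )
    dbh_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEF_DBH_LOGNORMAL)
    )
    height_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEF_HEIGHT)
    )
    litter_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEF_LITTER.items()}
    )
    soil_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEF_SOIL.items()}
    )
    soil_depth_range_m: tuple[float, float] = (0.05, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if len(self.islands) < 1 or len(set(self.islands)) != len(self.islands):
            raise ConfigError("islands: need >= 1 unique label")
        if len(self.forest_types) < 1 or len(set(self.forest_types)) != len(
            self.forest_types
        ):
            raise ConfigError("forest_types: need >= 1 unique label")
        for name in ("plots_per_cell", "subplots_per_plot", "species_pool_size"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if self.subplot_area_m2 <= 0:
            raise ConfigError("subplot_area_m2: must be > 0")
        if not np.isclose(
            self.plot_area_m2, self.subplots_per_plot * self.subplot_area_m2
        ):
            raise ConfigError(
                "plot_area_m2: must equal subplots_per_plot * subplot_area_m2"
            )
        for name in ("type_effect", "island_effect"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        lo, hi = self.soil_depth_range_m
        if not (0 < lo <= hi <= 0.30):
            raise ConfigError("soil_depth_range_m: must satisfy 0 < lo <= hi <= 0.30")

    def with_updates(self, **kwargs) -> "SurveyConfig":
        return replace(self, **kwargs)


@dataclass
class SurveyDataset:
    """A generated (or loaded) survey: design table plus all records."""

    taxa: list[Taxon]
    cover: AbundanceMatrix
    trees: list[TreeRecord]
    litter: list[LitterSample]
    soil: list[SoilSample]
    design: pd.DataFrame  # columns: subplot_id, plot_id, forest_type, island
    config: SurveyConfig | None = None

    @property
    def plot_design(self) -> pd.DataFrame:
        """One row per plot with its forest type and island."""
        return (
            self.design.drop(columns="subplot_id")
            .drop_duplicates("plot_id")
            .reset_index(drop=True)
        )

    def validate(self) -> None:
        known_subplots = set(self.design["subplot_id"])
        if set(self.cover.units) - known_subplots:
            raise ValueError("cover contains units absent from the design table")
        taxon_ids = {t.taxon_id for t in self.taxa}
        if set(self.cover.taxa) - taxon_ids:
            raise ValueError("cover contains unknown taxon ids")
        known_plots = set(self.design["plot_id"])
        for rec in self.trees:
            if rec.plot_id not in known_plots:
                raise ValueError(f"tree {rec.tree_id}: unknown plot {rec.plot_id}")
            if rec.taxon_id not in taxon_ids:
                raise ValueError(f"tree {rec.tree_id}: unknown taxon {rec.taxon_id}")
        for rec in [*self.litter, *self.soil]:
            if rec.plot_id not in known_plots:
                raise ValueError(f"sample references unknown plot {rec.plot_id}")
        per_plot = self.design.groupby("plot_id")[["forest_type", "island"]].nunique()
        if (per_plot > 1).any().any():
            raise ValueError("a plot maps to more than one forest type or island")


# --- generation ----------------------------------------------------------

_STREAMS = ("pool", "cover", "trees", "litter", "soil")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named sub-stream of the root seed."""
    key = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _dominant_specs(forest_types: Sequence[str]) -> list[tuple[str, str, str, str]]:
    """(home type, status, growth form, leaf type) of the planted dominants."""
    specs: list[tuple[str, str, str, str]] = []
    if "PF" in forest_types:
        specs.append(("PF", "exotic", "tree", "conifer"))
    if "EW" in forest_types:
        specs.append(("EW", "exotic", "tree", "broadleaf"))
    if "NF" in forest_types:
        specs += [("NF", "endemic", "tree", "broadleaf")] * 3
    if not specs:  # non-standard labels: one generic dominant per type
        specs = [(ft, "native", "tree", "broadleaf") for ft in forest_types]
    return specs


def generate_species_pool(config: SurveyConfig) -> list[Taxon]:
    """Build the regional species pool.

    The first taxa in the pool are the per-type dominants (affinity 1.0
    for their home type); the remainder get a random home type, a
    geometric rank-abundance position within it, and weak off-home
    affinities scaled by the type's openness.
    """
    config.validate()
    rng = _rng(config.seed, "pool")
    types = list(config.forest_types)
    dominants = _dominant_specs(types)
    if config.species_pool_size < len(dominants):
        raise ConfigError(
            f"species_pool_size: {config.species_pool_size} cannot host "
            f"{len(dominants)} per-type dominants"
        )

    openness = {ft: _TYPE_OPENNESS.get(ft, 1.0) for ft in types}
    taxa: list[Taxon] = []
    for i, (home, status, form, leaf) in enumerate(dominants):
        affinity = {
            ft: 1.0 if ft == home else round(0.03 * openness[ft], 6) for ft in types
        }
        taxa.append(
            Taxon(
                taxon_id=f"sp{i + 1:03d}",
                name=f"Dominant {home} {i + 1}",
                status=status,
                growth_form=form,
                leaf_type=leaf,
                affinity=affinity,
            )
        )

    n_rest = config.species_pool_size - len(dominants)
    # NF hosts the largest share of the pool, PF the smallest.
    home_probs = np.array(
        [{"NF": 0.5, "EW": 0.3, "PF": 0.2}.get(ft, 1.0) for ft in types], float
    )
    home_probs /= home_probs.sum()
    homes = rng.choice(len(types), size=n_rest, p=home_probs)
    statuses = rng.choice(STATUSES, size=n_rest, p=[0.30, 0.30, 0.40])
    forms = rng.choice(GROWTH_FORMS, size=n_rest, p=[0.25, 0.20, 0.35, 0.20])
    for j in range(n_rest):
        home = types[homes[j]]
        form = str(forms[j])
        leaf = "conifer" if (form == "tree" and rng.random() < 0.05) else "broadleaf"
        affinity = {}
        for ft in types:
            if ft == home:
                affinity[ft] = round(float(rng.uniform(0.5, 1.0)), 6)
            else:
                affinity[ft] = round(
                    float(rng.uniform(0.02, 0.25)) * openness[ft], 6
                )
        taxa.append(
            Taxon(
                taxon_id=f"sp{len(dominants) + j + 1:03d}",
                name=f"Taxon {len(dominants) + j + 1}",
                status=str(statuses[j]),
                growth_form=form,
                leaf_type=leaf,
                affinity=affinity,
            )
        )
    return taxa


def _build_design(config: SurveyConfig) -> pd.DataFrame:
    rows = []
    p = 0
    for island in config.islands:
        for ft in config.forest_types:
            for _ in range(config.plots_per_cell):
                p += 1
                plot_id = f"P{p:03d}"
                for s in range(config.subplots_per_plot):
                    rows.append(
                        {
                            "subplot_id": f"{plot_id}S{s + 1}",
                            "plot_id": plot_id,
                            "forest_type": ft,
                            "island": island,
                        }
                    )
    return pd.DataFrame(rows)


def _rank_scales(taxa: list[Taxon], config: SurveyConfig) -> np.ndarray:
    """Geometric rank-abundance scale per taxon within its home type."""
    home = [max(t.affinity, key=lambda ft: t.affinity[ft]) for t in taxa]
    scales = np.empty(len(taxa))
    for ft in config.forest_types:
        ratio = float(dict(config.dominance).get(ft, 0.7))
        idx = [i for i, h in enumerate(home) if h == ft]
        for rank, i in enumerate(idx):
            scales[i] = ratio**rank
    return scales


def _generate_cover(
    taxa: list[Taxon], design: pd.DataFrame, config: SurveyConfig
) -> AbundanceMatrix:
    rng = _rng(config.seed, "cover")
    n_units = len(design)
    n_taxa = len(taxa)
    scales = _rank_scales(taxa, config)

    # Per-taxon x island occurrence modifier, active only when
    # island_effect > 0 (exponent form keeps the null exchangeable).
    isl_mod = rng.uniform(0.5, 1.5, size=(n_taxa, len(config.islands)))
    isl_index = {isl: k for k, isl in enumerate(config.islands)}

    aff = np.array(
        [[t.affinity[ft] for ft in config.forest_types] for t in taxa], float
    )
    ft_index = {ft: k for k, ft in enumerate(config.forest_types)}

    base_occ = 0.12 + 0.55 * scales  # commoner taxa occupy more subplots
    base_cover = 2.0 + 55.0 * scales  # and reach larger mean percent cover

    values = np.zeros((n_units, n_taxa))
    unit_ft = design["forest_type"].map(ft_index).to_numpy()
    unit_isl = design["island"].map(isl_index).to_numpy()
    eps = 1e-9
    for u in range(n_units):
        a = aff[:, unit_ft[u]]
        m = isl_mod[:, unit_isl[u]]
        occ = np.clip(
            base_occ * np.power(a + eps, config.type_effect)
            * np.power(m, config.island_effect),
            0.0,
            0.95,
        )
        present = rng.random(n_taxa) < occ
        mean_cover = base_cover * np.power(a + eps, config.type_effect)
        draw = np.exp(rng.normal(np.log(mean_cover + eps), 0.6))
        values[u, present] = np.minimum(draw[present], 100.0)

    df = pd.DataFrame(
        values, index=design["subplot_id"].tolist(), columns=[t.taxon_id for t in taxa]
    )
    return AbundanceMatrix(df, level="subplot")


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lower: float, size: int
) -> np.ndarray:
    """Lognormal draws conditioned on exceeding ``lower`` (inverse CDF)."""
    from scipy import stats

    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    lo = dist.cdf(lower)
    u = rng.uniform(lo, 1.0, size=size)
    return dist.ppf(u)


def _generate_trees(
    taxa: list[Taxon], design: pd.DataFrame, config: SurveyConfig
) -> list[TreeRecord]:
    rng = _rng(config.seed, "trees")
    scales = _rank_scales(taxa, config)
    woody = np.array([t.growth_form in ("tree", "shrub") for t in taxa])
    aff = np.array(
        [[t.affinity[ft] for ft in config.forest_types] for t in taxa], float
    )
    ft_index = {ft: k for k, ft in enumerate(config.forest_types)}

    plots = design.drop_duplicates("plot_id")
    records: list[TreeRecord] = []
    counter = 0
    for _, row in plots.iterrows():
        ft = row["forest_type"]
        k = ft_index[ft]
        density = float(dict(config.tree_density_mean).get(ft, 3000.0))
        n_trees = rng.poisson(density * config.plot_area_m2 / 10_000.0)
        if n_trees == 0:
            continue
        # canopy composition is more concentrated than understory cover:
        # squaring the weights drives planted stands toward monoculture
        w = woody * (aff[:, k] * scales) ** 2
        if w.sum() <= 0:
            continue
        w = w / w.sum()
        picks = rng.choice(len(taxa), size=n_trees, p=w)
        mu, sigma = dict(config.dbh_lognormal_params)[ft]
        dbh = _truncated_lognormal(rng, mu, sigma, 2.5, n_trees)
        h_mean, h_sd = dict(config.height_params)[ft]
        heights = np.maximum(rng.normal(h_mean, h_sd, size=n_trees), 1.4)
        extra = rng.poisson(dict(_DEF_EXTRA_BRANCHES).get(ft, 0.2), size=n_trees)
        for j in range(n_trees):
            counter += 1
            nb = 1 + int(extra[j])
            if nb == 1:
                branches = (float(dbh[j]),)
            else:
                # split so the quadratic sum preserves the drawn D
                wts = rng.dirichlet(np.full(nb, 2.0))
                branches = tuple(float(dbh[j] * np.sqrt(x)) for x in wts)
            records.append(
                TreeRecord(
                    tree_id=f"T{counter:05d}",
                    plot_id=row["plot_id"],
                    taxon_id=taxa[picks[j]].taxon_id,
                    branch_dbh_cm=branches,
                    height_m=float(heights[j]),
                )
            )
    return records


def _generate_litter(design: pd.DataFrame, config: SurveyConfig) -> list[LitterSample]:
    rng = _rng(config.seed, "litter")
    out = []
    for _, row in design.drop_duplicates("plot_id").iterrows():
        params = dict(config.litter_params).get(row["forest_type"])
        if params is None:
            params = {"dry_mass": (500.0, 100.0), "carbon_conc": (350.0, 30.0)}
        m_mean, m_sd = params["dry_mass"]
        c_mean, c_sd = params["carbon_conc"]
        out.append(
            LitterSample(
                plot_id=row["plot_id"],
                dry_mass_g_per_m2=float(max(rng.normal(m_mean, m_sd), 0.0)),
                carbon_conc_gC_per_kg=float(np.clip(rng.normal(c_mean, c_sd), 0, 1000)),
            )
        )
    return out


def _generate_soil(design: pd.DataFrame, config: SurveyConfig) -> list[SoilSample]:
    rng = _rng(config.seed, "soil")
    lo, hi = config.soil_depth_range_m
    out = []
    for _, row in design.drop_duplicates("plot_id").iterrows():
        params = dict(config.soil_params).get(row["island"])
        if params is None:
            params = {"bulk_density": (900.0, 90.0), "organic_matter": (150.0, 25.0)}
        bd_mean, bd_sd = params["bulk_density"]
        om_mean, om_sd = params["organic_matter"]
        out.append(
            SoilSample(
                plot_id=row["plot_id"],
                bulk_density_kg_per_m3=float(max(rng.normal(bd_mean, bd_sd), 50.0)),
                organic_matter_g_per_kg=float(np.clip(rng.normal(om_mean, om_sd), 0, 1000)),
                depth_m=float(rng.uniform(lo, hi)),
                ph=float(np.clip(rng.normal(5.5, 0.5), 3.5, 8.5)),
            )
        )
    return out


def generate_survey(config: SurveyConfig | None = None) -> SurveyDataset:
    """Generate a complete seeded survey dataset.

    Identical configurations (including the seed) produce bit-identical
    datasets; each record family (pool, cover, trees, litter, soil)
    consumes its own derived random stream.
    """
    config = config or SurveyConfig()
    config.validate()
    taxa = generate_species_pool(config)
    design = _build_design(config)
    cover = _generate_cover(taxa, design, config)
    trees = _generate_trees(taxa, design, config)
    litter = _generate_litter(design, config)
    soil = _generate_soil(design, config)
    ds = SurveyDataset(
        taxa=taxa,
        cover=cover,
        trees=trees,
        litter=litter,
        soil=soil,
        design=design,
        config=config,
    )
    ds.validate()
    if not trees:
        warnings.warn("generated survey contains no trees", stacklevel=2)
    return ds
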