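"""Reading and writing survey datasets and analysis artefacts.

A survey directory holds six UTF-8 CSV tables: ``design.csv``,
``taxa.csv``, ``cover.csv`` (long format, non-zero records only),
``trees.csv`` (branch diameters as a ``;``-delimited list column),
``litter.csv`` and ``soil.csv``.  ``write_survey``/``read_survey``
round-trip a dataset losslessly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datagen import (
    AbundanceMatrix,
    LitterSample,
    SoilSample,
    SurveyConfig,
    SurveyDataset,
    Taxon,
    TreeRecord,
)

__all__ = [
    "SchemaError",
    "write_survey",
    "read_survey",
    "config_from_yaml",
    "write_distance_csv",
    "read_distance_csv",
]


class SchemaError(ValueError):
    """A required file or column is missing or referentially broken."""


_REQUIRED = {
    "design.csv": ["subplot_id", "plot_id", "forest_type", "island"],
    "taxa.csv": ["taxon_id", "name", "status", "growth_form", "leaf_type"],
    "cover.csv": ["subplot_id", "taxon_id", "cover"],
    "trees.csv": ["tree_id", "plot_id", "taxon_id", "branch_dbh_cm", "height_m"],
    "litter.csv": ["plot_id", "dry_mass_g_per_m2", "carbon_conc_gC_per_kg"],
    "soil.csv": ["plot_id", "bulk_density_kg_per_m3", "organic_matter_g_per_kg", "depth_m"],
}


def write_survey(dataset: SurveyDataset, out_dir: str | Path) -> list[Path]:
    """Write the six survey tables; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    dataset.design.to_csv(out / "design.csv", index=False)

    types = (
        list(dataset.config.forest_types)
        if dataset.config
        else sorted(dataset.taxa[0].affinity)
    )
    taxa_rows = []
    for t in dataset.taxa:
        row = {
            "taxon_id": t.taxon_id,
            "name": t.name,
            "status": t.status,
            "growth_form": t.growth_form,
            "leaf_type": t.leaf_type,
        }
        for ft in types:
            row[f"affinity_{ft}"] = t.affinity[ft]
        taxa_rows.append(row)
    pd.DataFrame(taxa_rows).to_csv(out / "taxa.csv", index=False)

    long = dataset.cover.df.stack()
    long = long[long > 0].rename("cover").reset_index()
    long.columns = ["subplot_id", "taxon_id", "cover"]
    long.to_csv(out / "cover.csv", index=False)

    pd.DataFrame(
        [
            {
                "tree_id": t.tree_id,
                "plot_id": t.plot_id,
                "taxon_id": t.taxon_id,
                "branch_dbh_cm": ";".join(repr(d) for d in t.branch_dbh_cm),
                "height_m": t.height_m,
            }
            for t in dataset.trees
        ],
        columns=_REQUIRED["trees.csv"],
    ).to_csv(out / "trees.csv", index=False)

    pd.DataFrame(
        [
            {
                "plot_id": s.plot_id,
                "dry_mass_g_per_m2": s.dry_mass_g_per_m2,
                "carbon_conc_gC_per_kg": s.carbon_conc_gC_per_kg,
            }
            for s in dataset.litter
        ],
        columns=_REQUIRED["litter.csv"],
    ).to_csv(out / "litter.csv", index=False)

    pd.DataFrame(
        [
            {
                "plot_id": s.plot_id,
                "bulk_density_kg_per_m3": s.bulk_density_kg_per_m3,
                "organic_matter_g_per_kg": s.organic_matter_g_per_kg,
                "depth_m": s.depth_m,
                "ph": s.ph if s.ph is not None else "",
            }
            for s in dataset.soil
        ],
        columns=_REQUIRED["soil.csv"] + ["ph"],
    ).to_csv(out / "soil.csv", index=False)

    for name in _REQUIRED:
        written.append(out / name)
    return written


def _load(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise SchemaError(f"{name}: file not found in {path}")
    df = pd.read_csv(f, float_precision="round_trip")
    missing = [c for c in _REQUIRED[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    return df


def read_survey(survey_dir: str | Path) -> SurveyDataset:
    """Load and validate a survey directory written by :func:`write_survey`."""
    path = Path(survey_dir)
    design = _load(path, "design.csv")
    taxa_df = _load(path, "taxa.csv")
    cover_df = _load(path, "cover.csv")
    trees_df = _load(path, "trees.csv")
    litter_df = _load(path, "litter.csv")
    soil_df = _load(path, "soil.csv")

    types = sorted(design["forest_type"].unique())
    taxa = []
    for _, r in taxa_df.iterrows():
        affinity = {
            ft: float(r[f"affinity_{ft}"])
            for ft in types
            if f"affinity_{ft}" in taxa_df.columns
        }
        taxa.append(
            Taxon(
                taxon_id=r["taxon_id"],
                name=r["name"],
                status=r["status"],
                growth_form=r["growth_form"],
                leaf_type=r["leaf_type"],
                affinity=affinity,
            )
        )
    taxon_ids = [t.taxon_id for t in taxa]

    unknown = set(cover_df["taxon_id"]) - set(taxon_ids)
    if unknown:
        raise SchemaError(f"cover.csv: unknown taxon_id(s) {sorted(unknown)}")
    unknown_units = set(cover_df["subplot_id"]) - set(design["subplot_id"])
    if unknown_units:
        raise SchemaError(f"cover.csv: unknown subplot_id(s) {sorted(unknown_units)}")

    wide = cover_df.pivot_table(
        index="subplot_id", columns="taxon_id", values="cover", fill_value=0.0,
        aggfunc="sum",
    )
    wide = wide.reindex(
        index=design["subplot_id"].tolist(), columns=taxon_ids, fill_value=0.0
    )
    wide.index.name = None
    wide.columns.name = None
    cover = AbundanceMatrix(wide, level="subplot")

    trees = [
        TreeRecord(
            tree_id=str(r["tree_id"]),
            plot_id=r["plot_id"],
            taxon_id=r["taxon_id"],
            branch_dbh_cm=tuple(float(d) for d in str(r["branch_dbh_cm"]).split(";")),
            height_m=float(r["height_m"]),
        )
        for _, r in trees_df.iterrows()
    ]
    if not trees:
        warnings.warn("trees.csv is empty: dataset loaded with zero trees", stacklevel=2)

    litter = [
        LitterSample(r["plot_id"], float(r["dry_mass_g_per_m2"]),
                     float(r["carbon_conc_gC_per_kg"]))
        for _, r in litter_df.iterrows()
    ]
    soil = [
        SoilSample(
            r["plot_id"],
            float(r["bulk_density_kg_per_m3"]),
            float(r["organic_matter_g_per_kg"]),
            float(r["depth_m"]),
            ph=float(r["ph"]) if "ph" in soil_df.columns and pd.notna(r.get("ph")) else None,
        )
        for _, r in soil_df.iterrows()
    ]

    ds = SurveyDataset(taxa=taxa, cover=cover, trees=trees, litter=litter,
                       soil=soil, design=design)
    try:
        ds.validate()
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc
    return ds


def config_from_yaml(path: str | Path) -> SurveyConfig:
    """Build a :class:`SurveyConfig` from a YAML file of field overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("islands", "forest_types"):
        if key in raw:
            raw[key] = tuple(raw[key])
    for key in ("dbh_lognormal_params", "height_params"):
        if key in raw:
            raw[key] = {k: tuple(v) for k, v in raw[key].items()}
    cfg = SurveyConfig(**raw)
    cfg.validate()
    return cfg


def write_distance_csv(dist, path: str | Path) -> None:
    dist.to_frame().to_csv(path)


def read_distance_csv(path: str | Path):
    from .community import DistanceMatrix

    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(df.index.astype(str)), df.to_numpy(float))
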