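"""End-to-end orchestration: simulate -> diversity -> partition ->
cluster -> ordination -> PERMANOVA -> IndVal -> structure -> carbon ->
group comparisons, with a JSON run manifest of output digests."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, diversity, structure
from .carbon import CarbonParameters, EquationRegistry, carbon_report, default_registry
from .datagen import SurveyConfig, SurveyDataset, generate_survey
from .groupstats import compare_metric
from .io import write_survey

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    seed: int
    config: dict
    outputs: dict[str, str]  # relative path -> sha256
    started: str
    finished: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derived_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(
    config: SurveyConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "forestplots_run",
    n_perm: int = 999,
    stages: tuple[str, ...] = (
        "diversity", "partition", "cluster", "ordinate",
        "permanova", "indval", "structure", "carbon", "compare",
    ),
    registry: EquationRegistry | None = None,
    params: CarbonParameters | None = None,
) -> tuple[RunManifest, SurveyDataset]:
    """Run the full survey analysis and write all tables to ``out_dir``."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = (config or SurveyConfig()).with_updates(seed=seed)

    dataset = generate_survey(config)
    files = write_survey(dataset, out / "survey")

    design = dataset.design
    plot_design = dataset.plot_design.set_index("plot_id")

    if "diversity" in stages:
        pdv = diversity.plot_diversity(dataset.cover, design)
        div = pd.DataFrame([vars(p) for p in pdv])
        div = div.merge(plot_design.reset_index(), on="plot_id")
        div.to_csv(out / "diversity.csv", index=False)
        files.append(out / "diversity.csv")

    if "partition" in stages:
        hierarchy = design.copy()
        hierarchy["cell"] = hierarchy["island"] + "|" + hierarchy["forest_type"]
        part = diversity.additive_partition(
            dataset.cover,
            hierarchy[["subplot_id", "plot_id", "cell", "forest_type"]],
            levels=["plot_id", "cell", "forest_type"],
        )
        part.to_frame().to_csv(out / "partition.csv", index=False)
        files.append(out / "partition.csv")

    plot_cover = dataset.cover.to_plot_level(design)
    dist = community.hellinger_distance(plot_cover)

    if "cluster" in stages:
        (dname, lname), scores = community.select_clustering(plot_cover)
        tree = community.upgma(community.DISTANCES[dname](plot_cover))
        k, diag = community.choose_k(tree, dist, k_max=min(8, dist.n - 1))
        scores.to_csv(out / "clustering_selection.csv", index=False)
        diag.to_csv(out / "cluster_diagnostics.csv", index=False)
        (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        labels = tree.cut(k)
        pd.DataFrame({"plot_id": dist.units, "cluster": labels}).to_csv(
            out / "clusters.csv", index=False
        )
        files += [out / "clustering_selection.csv", out / "cluster_diagnostics.csv",
                  out / "dendrogram.nwk", out / "clusters.csv"]

    if "ordinate" in stages:
        ord_ = community.nmds(dist, seed=_derived_seed(seed, "nmds"))
        coords = ord_.coordinates.copy()
        coords["stress"] = ord_.stress
        coords.to_csv(out / "nmds.csv")
        files.append(out / "nmds.csv")

    if "permanova" in stages:
        factors = plot_design.loc[list(dist.units), ["forest_type", "island"]]
        perm = community.permanova(
            dist, factors, n_perm=n_perm, seed=_derived_seed(seed, "permanova")
        )
        perm.table.to_csv(out / "permanova.csv")
        files.append(out / "permanova.csv")

    if "indval" in stages:
        groups = plot_design.loc[list(plot_cover.units), "forest_type"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iv = community.indval(
                plot_cover, groups, n_perm=n_perm, seed=_derived_seed(seed, "indval")
            )
        iv.table.to_csv(out / "indval.csv")
        files.append(out / "indval.csv")

    struct = None
    if "structure" in stages:
        struct = structure.structure_report(dataset)
        struct.to_csv(out / "structure.csv", index=False)
        files.append(out / "structure.csv")

    carbon_tbl = None
    if "carbon" in stages:
        rep = carbon_report(dataset, registry or default_registry(), params)
        rep.per_plot.to_csv(out / "carbon.csv", index=False)
        rep.summary.to_csv(out / "carbon_summary.csv", index=False)
        carbon_tbl = rep.per_plot
        files += [out / "carbon.csv", out / "carbon_summary.csv"]

    if "compare" in stages:
        metrics: list[tuple[str, pd.DataFrame, str]] = []
        if "diversity" in stages:
            metrics += [(c, div, c) for c in ("alpha", "beta", "gamma", "shannon", "evenness")]
        if struct is not None:
            metrics += [(c, struct, c) for c in ("density_per_ha", "ba_m2", "ba_gamma",
                                                 "ba_shannon", "height_mean_m")]
        if carbon_tbl is not None:
            metrics += [(c, carbon_tbl, c) for c in
                        ("c_trees_Mg_ha", "c_litter_Mg_ha", "c_soil_Mg_ha")]
        rows = []
        for name, table, col in metrics:
            vals = table[col].to_numpy(float)
            ok = np.isfinite(vals)
            res = compare_metric(
                vals[ok], table["island"].to_numpy()[ok],
                table["forest_type"].to_numpy()[ok],
            )
            s = res["summary"].copy()
            s.insert(0, "metric", name)
            for term in (res["anova"].table.index[:3]):
                s[f"F_{term}"] = res["anova"].f(term)
                s[f"p_{term}"] = res["anova"].p(term)
            rows.append(s)
        pd.concat(rows, ignore_index=True).to_csv(out / "comparisons.csv", index=False)
        files.append(out / "comparisons.csv")

    manifest = RunManifest(
        seed=seed,
        config={k: str(v) for k, v in asdict(config).items()},
        outputs={str(f.relative_to(out)): _sha256(f) for f in files},
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest, dataset
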