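"""End-to-end orchestration: simulate (or load) -> preprocess -> diversity
-> trajectories -> association -> resistome, with one structured config,
named per-stage random substreams, and a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import diversity, io, preprocess, trajectories
from .resistome import family_proportions, longitudinal_summary
from .simulate import (SimulationDesign, make_truth, simulate_counts,
                       simulate_resistome, simulate_tree_and_taxonomy)
from .studies import derive_seed
from .tables import CountTable


@dataclass
class RunConfig:
    """Flat, losslessly YAML-serializable configuration of the full run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "preprocess": True, "diversity": True,
        "trajectories": True, "association": True, "resistome": True})

    # inputs when not simulating
    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    taxonomy_path: str | None = None
    table_format: str = "tsv"

    # simulation design
    n_animals_per_group: dict = field(default_factory=lambda: {"CON": 3, "ABX": 3, "ABXFT": 2})
    n_taxa: int = 40
    depth_range: tuple = (15_000, 40_000)
    perturbation_effect: float = 4.0
    planted_rho: float = 0.8
    n_planted_pairs: int = 2
    n_resistant: int = 2
    fraction_unassigned: float = 0.05

    # preprocess
    min_reads: int = 10_000
    rarefy_depth: int = 15_000
    min_prevalence: int = 5
    other_frac: float = 1e-4
    n_instances: int = 16
    dirichlet_prior: float = 0.5

    # diversity
    shannon_base: float = 2.0
    baseline_day: int = -4

    # trajectories
    n_knots: int = 8
    n_perm: int = 99

    # association
    lengthscale: float = 10.0
    nugget: float = 0.1
    n_posterior_draws: int = 25
    strong_threshold: float = 0.5
    assoc_groups: tuple = ("ABX", "ABXFT")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("depth_range", "assoc_groups"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def demo(cls, outdir: str | Path, seed: int = 0) -> "RunConfig":
        """Small bundled synthetic end-to-end demonstration."""
        return cls(outdir=str(outdir), seed=seed)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _planted_pairs(cfg: RunConfig) -> list[tuple[int, int, float]]:
    return [(2 * k, 2 * k + 1, cfg.planted_rho) for k in range(cfg.n_planted_pairs)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages, write all artifacts under
    ``config.outdir``, and return (and write) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name: str) -> bool:
        return bool(config.stages.get(name, False))

    # ----- inputs -------------------------------------------------------
    try:
        if stage("simulate"):
            design = SimulationDesign(
                n_animals_per_group=dict(config.n_animals_per_group),
                n_taxa=config.n_taxa,
                depth_range=tuple(config.depth_range),
                perturbation_effect=config.perturbation_effect,
                seed=derive_seed(config.seed, "simulate"))
            truth = make_truth(design, planted_pairs=_planted_pairs(config),
                               n_resistant=config.n_resistant)
            dataset = simulate_counts(design, truth)
            counts, metadata = dataset.counts, dataset.metadata
            tree, taxonomy = simulate_tree_and_taxonomy(
                config.n_taxa, seed=derive_seed(config.seed, "tree"),
                fraction_unassigned=config.fraction_unassigned)
            resist, _ = simulate_resistome(design, truth)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            io.write_feature_table(counts, inputs / "counts.tsv")
            io.write_metadata(metadata, inputs / "metadata.tsv")
            io.write_tree(tree, inputs / "tree.nwk")
            io.write_taxonomy(taxonomy, inputs / "taxonomy.tsv")
            resist.counts.to_csv(inputs / "abr_genes.tsv", sep="\t")
            resist.family.rename("family").to_csv(inputs / "abr_families.tsv", sep="\t")
            resist.totals.rename("total_reads").to_csv(inputs / "abr_totals.tsv", sep="\t")
            report["stages"]["simulate"] = {
                "status": "ok", "n_taxa": counts.n_taxa,
                "n_samples": counts.n_samples, "n_abr_genes": len(resist.counts)}
        else:
            counts = io.load_feature_table(config.counts_path, config.table_format)
            metadata = io.load_metadata(config.metadata_path)
            tree = io.load_tree(config.tree_path) if config.tree_path else None
            taxonomy = (io.load_taxonomy(config.taxonomy_path)
                        if config.taxonomy_path else None)
            resist = None
            report["stages"]["simulate"] = {"status": "skipped"}
    except Exception as err:
        raise StageError("simulate/load", err) from err

    # ----- preprocess ---------------------------------------------------
    try:
        if stage("preprocess"):
            filtered = preprocess.filter_samples(counts, config.min_reads)
            rarefied = preprocess.rarefy(filtered, config.rarefy_depth,
                                         seed=derive_seed(config.seed, "rarefy"))
            io.write_feature_table(rarefied, out / "rarefied_counts.tsv")
            report["stages"]["preprocess"] = {
                "status": "ok",
                "samples_in": counts.n_samples,
                "samples_after_min_reads": filtered.n_samples,
                "samples_after_rarefaction": rarefied.n_samples,
                "rarefy_depth": config.rarefy_depth}
        else:
            rarefied = counts
            report["stages"]["preprocess"] = {"status": "skipped"}
    except Exception as err:
        raise StageError("preprocess", err) from err

    md = metadata[metadata["sample_id"].isin(rarefied.sample_ids)].reset_index(drop=True)

    # ----- diversity ----------------------------------------------------
    try:
        if stage("diversity"):
            alpha = diversity.shannon(rarefied, config.shannon_base)
            alpha.rename_axis("sample_id").to_csv(out / "alpha_diversity.tsv", sep="\t",
                                                  float_format=io.FLOAT_FORMAT)
            dm = diversity.unweighted_unifrac(rarefied, tree)
            io.write_distance_matrix(dm, out / "unweighted_unifrac.tsv")
            baseline = diversity.distance_from_baseline(dm, md, config.baseline_day)
            baseline.to_csv(out / "distance_from_baseline.tsv", sep="\t", index=False,
                            float_format=io.FLOAT_FORMAT)
            ord_res = diversity.pcoa(dm, k=2)
            coords = ord_res.samples.iloc[:, :2]
            coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                          float_format=io.FLOAT_FORMAT)
            # baseline group test on pretreatment alpha diversity
            pre = md[md["phase"] == "pretreatment"]
            h, p = diversity.kruskal_wallis_groups(
                alpha.loc[pre["sample_id"]], pre.set_index("sample_id")["group"])
            report["stages"]["diversity"] = {
                "status": "ok", "n_samples": len(alpha),
                "baseline_kruskal_H": round(h, 6), "baseline_kruskal_p": round(p, 6)}
        else:
            baseline = None
            alpha = None
            report["stages"]["diversity"] = {"status": "skipped"}
    except Exception as err:
        raise StageError("diversity", err) from err

    # ----- trajectories -------------------------------------------------
    try:
        if stage("trajectories") and alpha is not None:
            series = md.copy()
            series["value"] = alpha.loc[series["sample_id"]].to_numpy()
            fit = trajectories.fit_group_smooths(series, n_knots=config.n_knots)
            fit.to_frame().to_csv(out / "alpha_trajectories.tsv", sep="\t",
                                  index=False, float_format=io.FLOAT_FORMAT)
            tests = {}
            groups = sorted(series["group"].unique())
            for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
                if (series.drop_duplicates("animal_id")["group"] == a).sum() < 2:
                    continue
                if (series.drop_duplicates("animal_id")["group"] == b).sum() < 2:
                    continue
                res = trajectories.compare_groups_permutation(
                    series, a, b, n_perm=config.n_perm,
                    seed=derive_seed(config.seed, f"perm-{a}-{b}"))
                tests[f"{a}_vs_{b}"] = {"statistic": res["statistic"],
                                        "p_value": res["p_value"]}
            (out / "trajectory_tests.json").write_text(json.dumps(tests, indent=2,
                                                                  sort_keys=True))
            report["stages"]["trajectories"] = {"status": "ok", "n_tests": len(tests),
                                                "lam": fit.lam}
        else:
            report["stages"]["trajectories"] = {"status": "skipped"}
    except Exception as err:
        raise StageError("trajectories", err) from err

    # ----- association --------------------------------------------------
    try:
        if stage("association"):
            filtered, md_assoc, filt_log = preprocess.association_prefilter(
                counts, metadata, taxonomy,
                min_samples=config.min_prevalence,
                min_total_frac=config.other_frac)
            edge_tables = {}
            for group in config.assoc_groups:
                animals = sorted(md_assoc.loc[md_assoc["group"] == group,
                                              "animal_id"].unique())
                if not animals:
                    continue
                rng = np.random.default_rng(derive_seed(config.seed, f"dirichlet-{group}"))
                instances = []
                for animal in animals:
                    ser, days = preprocess.animal_series(filtered, md_assoc, animal)
                    instances.extend(preprocess.dirichlet_instances(
                        ser, days, n_instances=config.n_instances,
                        prior=config.dirichlet_prior, seed=rng, animal_id=animal))
                gp = assoc.GPConfig(lengthscale=config.lengthscale,
                                    nugget=config.nugget,
                                    n_posterior_draws=config.n_posterior_draws,
                                    seed=derive_seed(config.seed, f"gp-{group}"))
                post = assoc.fit_gp_posterior(instances, gp,
                                              provenance={"group": group})
                edges = assoc.summarize_associations(post, config.strong_threshold)
                io.write_edges(edges, out / f"associations_{group}.tsv")
                io.edges_to_graphml(edges, out / f"associations_{group}.graphml")
                edge_tables[group] = edges
            assoc_report = {"status": "ok", "filter_log": filt_log,
                            "n_strong": {g: int(e["strong"].sum())
                                         for g, e in edge_tables.items()}}
            if len(edge_tables) == 2:
                a, b = list(edge_tables)
                comparison = assoc.compare_networks(edge_tables[a], edge_tables[b])
                (out / "network_comparison.json").write_text(
                    json.dumps(comparison, indent=2, sort_keys=True))
                assoc_report["n_shared_strong"] = comparison["n_shared"]
            report["stages"]["association"] = assoc_report
        else:
            report["stages"]["association"] = {"status": "skipped"}
    except Exception as err:
        raise StageError("association", err) from err

    # ----- resistome ----------------------------------------------------
    try:
        if stage("resistome") and resist is not None:
            props = family_proportions(resist)
            props.to_csv(out / "abr_family_proportions.tsv", sep="\t",
                         float_format=io.FLOAT_FORMAT)
            summary, trends = longitudinal_summary(resist, metadata)
            summary.to_csv(out / "abr_longitudinal_summary.tsv", sep="\t",
                           float_format=io.FLOAT_FORMAT)
            trends.to_csv(out / "abr_trends.tsv", sep="\t", index=False,
                          float_format=io.FLOAT_FORMAT)
            report["stages"]["resistome"] = {
                "status": "ok",
                "trends": dict(zip(trends["group"], trends["trend"]))}
        else:
            report["stages"]["resistome"] = {"status": "skipped"}
    except Exception as err:
        raise StageError("resistome", err) from err

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                    default=str))
    return report
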