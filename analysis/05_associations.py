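"""Bacterial association networks per treatment group and phase.

Study-order prefiltering (drop pretreatment samples, remove taxa in < 5
samples, collapse to genus, fold < 0.01%-share genera into Other), then
Dirichlet Monte-Carlo CLR instances per animal, the matrix-normal/
inverse-Wishart Gaussian-process posterior over taxon correlations, and
edge tables of significant (95% CI excludes 0) and strong (|median rho| >
0.5) associations — for all post-baseline phases and for recovery only —
plus the log-ratio trajectory of a planted resistant taxon.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gutshift import io
from gutshift.association import (GPConfig, compare_networks, fit_gp_posterior,
                                  log_ratio_trajectory, summarize_associations)
from gutshift.preprocess import (animal_series, association_prefilter,
                                 dirichlet_instances)
from gutshift.studies import derive_seed

SEED = 0
N_INSTANCES = 32
N_DRAWS = 50
BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def group_instances(table, md, group, rng):
    out = []
    for animal in sorted(md.loc[md["group"] == group, "animal_id"].unique()):
        ser, days = animal_series(table, md, animal)
        out.extend(dirichlet_instances(ser, days, n_instances=N_INSTANCES,
                                       seed=rng, animal_id=animal))
    return out


def main() -> None:
    counts = io.load_feature_table(BASE / "inputs" / "counts.tsv")
    md = io.load_metadata(BASE / "inputs" / "metadata.tsv")
    taxonomy = io.load_taxonomy(BASE / "inputs" / "taxonomy.tsv")

    filtered, md_f, log = association_prefilter(counts, md, taxonomy)
    print(f"prefilter: {counts.n_taxa} features -> {filtered.n_taxa} genera; "
          f"{100 * log['fraction_removed']:.2f}% of post-baseline counts removed")

    edges_by_key = {}
    for phase_name, md_phase in [("all", md_f),
                                 ("recovery", md_f[md_f["phase"] == "recovery"])]:
        table_phase = filtered.select_samples(md_phase["sample_id"].tolist())
        for group in ("ABX", "ABXFT"):
            rng = np.random.default_rng(
                derive_seed(SEED, f"dirichlet-{group}-{phase_name}"))
            inst = group_instances(table_phase, md_phase, group, rng)
            gp = GPConfig(n_posterior_draws=N_DRAWS,
                          seed=derive_seed(SEED, f"gp-{group}-{phase_name}"))
            edges = summarize_associations(fit_gp_posterior(inst, gp))
            io.write_edges(edges, BASE / f"associations_{group}_{phase_name}.tsv")
            edges_by_key[(group, phase_name)] = edges
            strong = edges[edges["strong"]]
            print(f"{group} ({phase_name} phases): {len(strong)} strong "
                  f"({int((strong['sign'] > 0).sum())} positive, "
                  f"{int((strong['sign'] < 0).sum())} negative)")

    comparison = {}
    for phase_name in ("all", "recovery"):
        rep = compare_networks(edges_by_key[("ABX", phase_name)],
                               edges_by_key[("ABXFT", phase_name)])
        comparison[phase_name] = rep
        print(f"shared strong associations ABX/ABXFT ({phase_name}): {rep['n_shared']}")
    (BASE / "network_comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True))

    # log-ratio trajectory of one planted resistant taxon in ABX animals
    # (full series including pretreatment, to show the treatment-phase rise)
    resistant = f"t{counts.n_taxa - 1}"
    rng = np.random.default_rng(derive_seed(SEED, "resistant-traj"))
    inst = []
    for animal in sorted(md.loc[md["group"] == "ABX", "animal_id"].unique()):
        ser, days = animal_series(counts, md, animal)
        inst.extend(dirichlet_instances(ser, days, n_instances=N_INSTANCES,
                                        seed=rng, animal_id=animal))
    traj = log_ratio_trajectory(inst, resistant)
    traj.to_csv(BASE / f"log_ratio_{resistant}.tsv", sep="\t", index=False,
                float_format=io.FLOAT_FORMAT)
    pre = traj.loc[traj["day"] < 0, "median"].mean()
    treat = traj.loc[(traj["day"] >= 0) & (traj["day"] <= 6), "median"].mean()
    print(f"resistant taxon {resistant}: CLR median pretreatment {pre:.2f} -> "
          f"treatment {treat:.2f} ({'rising' if treat > pre else 'not rising'})")


if __name__ == "__main__":
    main()
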