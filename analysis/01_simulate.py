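"""Generate the synthetic study cohort.

Three experimental groups of male study animals (untreated CON, antibiotic
ABX, antibiotic + fecal transfaunation ABXFT) sampled over ~125 days with a
7-day antibiotic window (days 0-6) and transfaunation on day 7.  The
ground truth plants two strong positive taxon-pair correlations and two
antibiotic-resistant taxa.  Writes counts, metadata, tree, taxonomy, and
the ABR gene table under results/analysis/inputs/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gutshift import io
from gutshift.simulate import (SimulationDesign, make_truth, simulate_counts,
                               simulate_resistome, simulate_tree_and_taxonomy)
from gutshift.studies import derive_seed

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = SimulationDesign(seed=derive_seed(SEED, "cohort"))
    truth = make_truth(design, planted_pairs=[(0, 1, 0.8), (2, 3, 0.8)],
                       n_resistant=2)
    dataset = simulate_counts(design, truth)
    tree, taxonomy = simulate_tree_and_taxonomy(design.n_taxa,
                                                seed=derive_seed(SEED, "tree"),
                                                fraction_unassigned=0.05)
    resist, _ = simulate_resistome(design, truth)

    io.write_feature_table(dataset.counts, OUT / "counts.tsv")
    io.write_metadata(dataset.metadata, OUT / "metadata.tsv")
    io.write_tree(tree, OUT / "tree.nwk")
    io.write_taxonomy(taxonomy, OUT / "taxonomy.tsv")
    resist.counts.to_csv(OUT / "abr_genes.tsv", sep="\t")
    resist.family.rename("family").to_csv(OUT / "abr_families.tsv", sep="\t")
    resist.totals.rename("total_reads").to_csv(OUT / "abr_totals.tsv", sep="\t")

    n_animals = dataset.metadata["animal_id"].nunique()
    print(f"cohort: {n_animals} animals, {dataset.counts.n_samples} samples, "
          f"{dataset.counts.n_taxa} taxa, depths "
          f"{dataset.counts.sample_sums().min()}-{dataset.counts.sample_sums().max()}")
    print(f"planted truth: strong pairs (t0,t1) and (t2,t3) at rho=0.8; "
          f"resistant taxa t{truth.resistant_taxa[0]}, t{truth.resistant_taxa[1]}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
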