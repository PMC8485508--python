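"""Alpha and beta diversity of the cohort.

Shannon-Weaver diversity per sample, unweighted UniFrac distances from the
phylogeny, each animal's distance from its own day -4 baseline community,
a PCoA ordination, and the baseline (pretreatment) Kruskal-Wallis group
test — during baseline the three groups should be statistically
indistinguishable.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gutshift import io
from gutshift.diversity import (distance_from_baseline, kruskal_wallis_groups,
                                pcoa, shannon, unweighted_unifrac)

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    rarefied = io.load_feature_table(BASE / "rarefied_counts.tsv")
    md = io.load_metadata(BASE / "inputs" / "metadata.tsv")
    md = md[md["sample_id"].isin(rarefied.sample_ids)]
    tree = io.load_tree(BASE / "inputs" / "tree.nwk")

    alpha = shannon(rarefied)
    alpha.rename_axis("sample_id").to_csv(BASE / "alpha_diversity.tsv", sep="\t",
                                          float_format=io.FLOAT_FORMAT)
    dm = unweighted_unifrac(rarefied, tree)
    io.write_distance_matrix(dm, BASE / "unweighted_unifrac.tsv")
    baseline = distance_from_baseline(dm, md, baseline_day=-4)
    baseline.to_csv(BASE / "distance_from_baseline.tsv", sep="\t", index=False,
                    float_format=io.FLOAT_FORMAT)
    ordination = pcoa(dm, k=2)
    ordination.samples.to_csv(BASE / "pcoa_coordinates.tsv", sep="\t",
                              float_format=io.FLOAT_FORMAT)

    phase = md.set_index("sample_id")["phase"]
    group = md.set_index("sample_id")["group"]
    for g in sorted(group.unique()):
        ids = group[group == g].index
        by_phase = alpha.loc[ids].groupby(phase.loc[ids]).mean()
        print(f"mean Shannon (bits) {g}: " +
              ", ".join(f"{p}={v:.2f}" for p, v in by_phase.items()))

    # per-animal baseline means: pretreatment samples within an animal are
    # temporally autocorrelated, so animals are the independent units
    pre = md[md["phase"] == "pretreatment"]
    per_animal = alpha.loc[pre["sample_id"]].groupby(
        pre.set_index("sample_id")["animal_id"]).mean()
    animal_group = pre.drop_duplicates("animal_id").set_index("animal_id")["group"]
    h, p = kruskal_wallis_groups(per_animal, animal_group.loc[per_animal.index])
    print(f"baseline alpha-diversity group test: Kruskal-Wallis H={h:.3f}, p={p:.3f}"
          f" -> groups {'indistinguishable' if p > 0.05 else 'differ'} at baseline")

    treat = baseline[baseline["phase"] == "treatment"].groupby("group")["distance"].mean()
    pre_d = baseline[baseline["phase"] == "pretreatment"].groupby("group")["distance"].mean()
    for g in treat.index:
        print(f"distance from baseline, {g}: pretreatment {pre_d[g]:.3f} -> "
              f"treatment {treat[g]:.3f}")


if __name__ == "__main__":
    main()
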