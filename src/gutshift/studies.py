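"""Simulation studies that characterize the pipeline's operating
properties on ground-truthed synthetic cohorts.

Each study runs the real pipeline code on generated data and measures a
calibration, recovery, or power figure: false-positive rate of the
association engine on null (diagonal-correlation) data, sensitivity and
sign fidelity on planted strong pairs, the resistant-taxon log-ratio
signature, elevation of distance-from-baseline under treatment, and
type-I error / power of the trajectory permutation contrast.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import diversity, trajectories
from .association import (GPConfig, classify_treatment_trend, fit_gp_posterior,
                          log_ratio_trajectory, summarize_associations)
from .preprocess import dirichlet_instances
from .simulate import (SimulationDesign, SyntheticTruth, make_truth,
                       planted_pair_correlation, simulate_counts,
                       simulate_tree_and_taxonomy)


def derive_seed(root: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    digest = hashlib.sha256(f"{root}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _group_instances(dataset, group: str, n_instances: int, prior: float,
                     rng: np.random.Generator):
    """Dirichlet CLR instances for every animal of one group."""
    from .preprocess import animal_series
    md = dataset.metadata
    out = []
    for animal in sorted(md.loc[md["group"] == group, "animal_id"].unique()):
        series, days = animal_series(dataset.counts, md, animal)
        out.extend(dirichlet_instances(series, days, n_instances=n_instances,
                                       prior=prior, seed=rng, animal_id=animal))
    return out


# ---------------------------------------------------------------------------
# association engine: calibration and recovery
# ---------------------------------------------------------------------------

def association_null_calibration(n_seeds: int = 20, n_taxa: int = 20,
                                 n_animals: int = 3, n_instances: int = 32,
                                 n_draws: int = 50, seed: int = 0) -> dict:
    """False-positive rate of the significance call on null data.

    Diagonal true correlation, no perturbation: the fraction of taxon pairs
    whose 95% credible interval excludes zero should stay near or below the
    nominal level.  Returns the per-seed fractions and their mean.
    """
    fractions = []
    for s in range(n_seeds):
        root = derive_seed(seed, f"null-calibration-{s}")
        design = SimulationDesign(n_animals_per_group={"CON": n_animals},
                                  n_taxa=n_taxa, perturbation_effect=0.0,
                                  seed=root)
        truth = make_truth(design, planted_pairs=None, n_resistant=0)
        dataset = simulate_counts(design, truth)
        rng = np.random.default_rng(derive_seed(root, "dirichlet"))
        instances = _group_instances(dataset, "CON", n_instances, 0.5, rng)
        config = GPConfig(n_posterior_draws=n_draws, seed=derive_seed(root, "gp"))
        post = fit_gp_posterior(instances, config)
        edges = summarize_associations(post)
        fractions.append(float(edges["significant"].mean()))
    return {"per_seed": fractions, "mean_fraction_significant": float(np.mean(fractions)),
            "n_pairs": n_taxa * (n_taxa - 1) // 2}


def default_planted_pairs(rho: float = 0.8) -> list[tuple[int, int, float]]:
    """Five positive and three negative disjoint planted pairs."""
    pos = [(2 * k, 2 * k + 1, rho) for k in range(5)]
    neg = [(10 + 2 * k, 11 + 2 * k, -rho) for k in range(3)]
    return pos + neg


def association_recovery(n_seeds: int = 20, n_taxa: int = 30,
                         n_animals: int = 5, n_instances: int = 32,
                         n_draws: int = 50, rho: float = 0.8,
                         strong_threshold: float = 0.5, seed: int = 0) -> dict:
    """Strong-edge sensitivity and sign fidelity on planted pairs.

    Plants 5 positive and 3 negative pairs at |rho| on an otherwise
    diagonal correlation and measures how often the pipeline flags them as
    strong associations with the right sign.
    """
    pairs = default_planted_pairs(rho)
    detected, flips = [], 0
    for s in range(n_seeds):
        root = derive_seed(seed, f"recovery-{s}")
        design = SimulationDesign(n_animals_per_group={"CON": n_animals},
                                  n_taxa=n_taxa, perturbation_effect=0.0,
                                  seed=root)
        truth = make_truth(design, planted_pairs=pairs, n_resistant=0)
        dataset = simulate_counts(design, truth)
        rng = np.random.default_rng(derive_seed(root, "dirichlet"))
        instances = _group_instances(dataset, "CON", n_instances, 0.5, rng)
        config = GPConfig(n_posterior_draws=n_draws, seed=derive_seed(root, "gp"))
        edges = summarize_associations(fit_gp_posterior(instances, config),
                                       strong_threshold=strong_threshold)
        edge_of = {frozenset((r.taxon_i, r.taxon_j)): r for r in edges.itertuples()}
        hit = 0
        for i, j, target in pairs:
            e = edge_of[frozenset((f"t{i}", f"t{j}"))]
            if e.strong:
                hit += 1
                if np.sign(target) != e.sign:
                    flips += 1
        detected.append(hit / len(pairs))
    return {"per_seed_sensitivity": detected,
            "sensitivity": float(np.mean(detected)),
            "n_sign_flips": flips,
            "n_planted": len(pairs)}


# ---------------------------------------------------------------------------
# resistant-taxon log-ratio signature
# ---------------------------------------------------------------------------

def resistant_taxon_signature(n_seeds: int = 50, n_taxa: int = 30,
                              n_instances: int = 32, seed: int = 0) -> dict:
    """How often an unperturbed (resistant) taxon shows a rising CLR median
    during the antibiotic window while the rest of the community crashes."""
    rising = 0
    for s in range(n_seeds):
        root = derive_seed(seed, f"resistant-{s}")
        design = SimulationDesign(n_animals_per_group={"ABX": 1}, n_taxa=n_taxa,
                                  seed=root)
        truth = make_truth(design, n_resistant=1)
        dataset = simulate_counts(design, truth)
        resistant_id = f"t{truth.resistant_taxa[0]}"
        rng = np.random.default_rng(derive_seed(root, "dirichlet"))
        instances = _group_instances(dataset, "ABX", n_instances, 0.5, rng)
        traj = log_ratio_trajectory(instances, resistant_id)
        if classify_treatment_trend(traj, design.perturbation_window) == "rising":
            rising += 1
    return {"fraction_rising": rising / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# distance-from-baseline elevation under treatment
# ---------------------------------------------------------------------------

def baseline_distance_elevation(n_seeds: int = 50, n_taxa: int = 40,
                                rarefy_depth: int = 15_000, seed: int = 0) -> dict:
    """How often treated animals' mean UniFrac distance from baseline during
    the antibiotic window exceeds their pretreatment mean.

    Counts are rarefied first: presence (count > 0) is only comparable
    across samples at a common depth.
    """
    from .preprocess import rarefy
    elevated = 0
    for s in range(n_seeds):
        root = derive_seed(seed, f"baseline-dist-{s}")
        design = SimulationDesign(n_animals_per_group={"ABX": 2}, n_taxa=n_taxa,
                                  seed=root)
        truth = make_truth(design, n_resistant=2)
        dataset = simulate_counts(design, truth)
        rarefied = rarefy(dataset.counts, rarefy_depth,
                          seed=derive_seed(root, "rarefy"))
        tree, _ = simulate_tree_and_taxonomy(n_taxa, seed=derive_seed(root, "tree"))
        dm = diversity.unweighted_unifrac(rarefied, tree)
        series = diversity.distance_from_baseline(dm, dataset.metadata)
        treat = series.loc[series["phase"] == "treatment", "distance"].mean()
        pre = series.loc[series["phase"] == "pretreatment", "distance"].mean()
        if treat > pre:
            elevated += 1
    return {"fraction_elevated": elevated / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# trajectory permutation contrast: type-I error and power
# ---------------------------------------------------------------------------

def simulate_series(n_animals_per_group: int = 5, offset: float = 0.0,
                    noise_sd: float = 1.0, animal_sd: float = 0.5,
                    days: tuple[int, ...] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Long-format response series for two groups A/B sharing a smooth
    nonlinear time trend; group B carries a persistent additive offset."""
    from .simulate import DEFAULT_SAMPLING_DAYS
    days = np.asarray(days if days is not None else DEFAULT_SAMPLING_DAYS, float)
    rng = np.random.default_rng(seed)
    rows = []
    for g, group in enumerate(("A", "B")):
        for a in range(n_animals_per_group):
            animal = f"{group}{a}"
            b = rng.normal(0, animal_sd)
            trend = np.sin(days / 20.0)
            y = trend + b + (offset if group == "B" else 0.0) \
                + rng.normal(0, noise_sd, size=len(days))
            for d, v in zip(days, y):
                rows.append({"day": d, "value": v, "animal_id": animal,
                             "group": group})
    return pd.DataFrame(rows)


def trajectory_test_rates(n_sims: int = 200, n_perm: int = 199,
                          offset: float = 0.0, alpha: float = 0.05,
                          n_animals_per_group: int = 5, seed: int = 0) -> dict:
    """Rejection rate of the animal-label permutation contrast.

    With ``offset = 0`` this is the type-I error; with a planted persistent
    offset it is power.
    """
    rejections = 0
    for s in range(n_sims):
        series = simulate_series(n_animals_per_group=n_animals_per_group,
                                 offset=offset,
                                 seed=derive_seed(seed, f"traj-{offset}-{s}"))
        res = trajectories.compare_groups_permutation(
            series, "A", "B", n_perm=n_perm,
            seed=derive_seed(seed, f"perm-{offset}-{s}"))
        if res["p_value"] <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims,
            "n_perm": n_perm, "offset": offset, "alpha": alpha}
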