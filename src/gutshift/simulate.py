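"""Ground-truthed synthetic longitudinal microbiome datasets.

The generator inverts the analysis model: per animal, latent log-abundances
follow a matrix-variate normal whose row covariance is a planted taxon
correlation matrix and whose column covariance is a squared-exponential
kernel over the sampling days, so that the downstream compositional
covariation engine has a recoverable ground truth.  Treated groups get a
log-scale "crash" of most taxa during the antibiotic window (days 0-6) with
exponential recovery; a configurable set of resistant taxa is left
unperturbed, which makes their centered log-ratio rise during treatment
(the *Bacteroides*/*Parabacteroides* signature).  Transfaunated animals are
partially reset toward their pretreatment state from the transfaunation day
onward.  Counts are multinomial draws from the softmax composition at a
uniformly drawn sequencing depth.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .resistome import ABR_FAMILIES, ResistomeTable
from .tables import GROUPS, CountTable, phase_of_day

DEFAULT_SAMPLING_DAYS = (-6, -4, -2, 0, 2, 4, 6, 8, 10, 13, 20, 34, 62, 90, 118)

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

# study-like baseline family mix of antibiotic-resistance gene reads:
# four dominant families plus minor representation of three more
ABR_FAMILY_WEIGHTS = {
    "Tetracycline": 0.514,
    "Beta-lactam": 0.295,
    "Aminoglycoside": 0.079,
    "Macrolide": 0.012,
    "Vancomycin": 0.04,
    "MDR": 0.04,
    "Sulphonamide": 0.02,
}


class InvalidDesignError(ValueError):
    """Simulation design violates an invariant."""


class InvalidTruthError(ValueError):
    """Planted ground truth violates an invariant."""


@dataclass
class SimulationDesign:
    """Study design constants for one simulated cohort.

    Defaults mirror the study layout: three experimental groups (untreated
    CON, antibiotic-only ABX, antibiotic + fecal transfaunation ABXFT)
    followed over ~125 days with dense sampling around the 7-day antibiotic
    course (days 0-6) and sparse sampling thereafter; transfaunation on
    day 7 uses the animal's own day -4 feces.
    """

    n_animals_per_group: dict[str, int] = field(
        default_factory=lambda: {"CON": 6, "ABX": 3, "ABXFT": 2})
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    n_taxa: int = 80
    depth_range: tuple[int, int] = (15_000, 60_000)
    perturbation_window: tuple[int, int] = (0, 6)
    # natural-log crash depth for sensitive taxa; e^-4 ~ 55x reduction,
    # deep enough to push rare community members below detection
    perturbation_effect: float = 4.0
    transfaunation_day: int = 7
    transfaunation_weight: float = 0.5
    recovery_rate_by_group: dict[str, float] = field(
        default_factory=lambda: {"CON": 0.0, "ABX": 0.08, "ABXFT": 0.08})
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_animals_per_group, int):
            self.n_animals_per_group = {g: self.n_animals_per_group for g in GROUPS}
        days = np.asarray(self.sampling_days, dtype=float)
        if not (np.diff(days) > 0).all():
            raise InvalidDesignError("sampling_days must be strictly increasing")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise InvalidDesignError("depth_range must satisfy 1 <= min <= max")
        if self.n_taxa < 3:
            raise InvalidDesignError("need at least 3 taxa")
        unknown = set(self.n_animals_per_group) - set(GROUPS)
        if unknown:
            raise InvalidDesignError(f"unknown groups {sorted(unknown)}")
        if not 0.0 <= self.transfaunation_weight <= 1.0:
            raise InvalidDesignError("transfaunation_weight must lie in [0, 1]")

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs in a fixed deterministic order."""
        out = []
        for g in GROUPS:
            for i in range(self.n_animals_per_group.get(g, 0)):
                out.append((f"{g}{i + 1}", g))
        return out


def planted_pair_correlation(n_taxa: int,
                             pairs: list[tuple[int, int, float]] | None) -> np.ndarray:
    """Identity correlation with |rho| planted on disjoint taxon pairs.

    Disjoint pairs keep the matrix positive definite for any |rho| < 1.
    """
    corr = np.eye(n_taxa)
    used: set[int] = set()
    for i, j, rho in pairs or []:
        if i == j or not -1.0 < rho < 1.0:
            raise InvalidTruthError(f"bad planted pair ({i}, {j}, {rho})")
        if i in used or j in used:
            raise InvalidTruthError("planted pairs must be disjoint")
        used.update((i, j))
        corr[i, j] = corr[j, i] = rho
    return corr


@dataclass
class SyntheticTruth:
    """Planted ground truth behind one simulated dataset."""

    true_correlation: np.ndarray
    true_lengthscale: float = 10.0
    perturbed_taxa: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    resistant_taxa: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    #: unit-mean per-taxon susceptibility multipliers on the crash depth;
    #: heterogeneous susceptibility is what reshapes composition and drives
    #: taxa below detection (None -> uniform susceptibility)
    susceptibility: np.ndarray | None = None
    latent_sd: float = 1.0
    baseline_logmean_sd: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.true_correlation, dtype=float)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise InvalidTruthError("true_correlation must be square")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise InvalidTruthError("true_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise InvalidTruthError("true_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise InvalidTruthError("true_correlation must be positive semi-definite")
        self.true_correlation = corr
        self.perturbed_taxa = np.asarray(self.perturbed_taxa, dtype=int)
        self.resistant_taxa = np.asarray(self.resistant_taxa, dtype=int)
        n = corr.shape[0]
        if self.susceptibility is not None:
            self.susceptibility = np.asarray(self.susceptibility, dtype=float)
            if self.susceptibility.shape != (n,) or (self.susceptibility < 0).any():
                raise InvalidTruthError(
                    "susceptibility must be a non-negative vector over taxa")
        for idx in (self.perturbed_taxa, self.resistant_taxa):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise InvalidTruthError("taxon index set out of range")

    @property
    def n_taxa(self) -> int:
        return self.true_correlation.shape[0]


def make_truth(design: SimulationDesign,
               planted_pairs: list[tuple[int, int, float]] | None = None,
               n_resistant: int = 2,
               seed: int | None = None) -> SyntheticTruth:
    """Default ground truth: planted pairs (if any) on an identity
    correlation; the last ``n_resistant`` taxa are antibiotic-resistant and
    every other taxon is perturbed by treatment."""
    n = design.n_taxa
    corr = planted_pair_correlation(n, planted_pairs)
    resistant = np.arange(n - n_resistant, n) if n_resistant else np.array([], dtype=int)
    perturbed = np.setdiff1d(np.arange(n), resistant)
    use_seed = design.seed if seed is None else seed
    rng = np.random.default_rng(use_seed + 7_777_777)
    susceptibility = rng.gamma(shape=2.0, scale=0.5, size=n)  # unit mean
    return SyntheticTruth(true_correlation=corr,
                          perturbed_taxa=perturbed,
                          resistant_taxa=resistant,
                          susceptibility=susceptibility,
                          seed=use_seed)


# ---------------------------------------------------------------------------
# tree + taxonomy
# ---------------------------------------------------------------------------

def simulate_tree_and_taxonomy(n_taxa: int, seed: int,
                               fraction_unassigned: float = 0.0,
                               n_genera: int | None = None,
                               ) -> tuple[TreeNode, pd.DataFrame]:
    """Random rooted binary tree over ``n_taxa`` leaves plus a 7-rank
    taxonomy table.

    Leaves are labelled ``t0..t{n-1}``.  A configurable fraction of leaves
    is "Unassigned" below Kingdom (their lineage is ``k__Bacteria`` alone);
    the rest share genera drawn from a pool smaller than the leaf count so
    genus-level collapsing is non-trivial.

    Returns the tree (all branch lengths > 0) and a two-column taxonomy
    frame (``feature_id``, ``lineage``) in QIIME2 dialect.
    """
    if n_taxa < 3:
        raise InvalidDesignError("a rooted binary tree needs at least 3 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}", length=None) for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.exponential(0.1) + 0.01)
    # random sequential pairwise joins -> rooted binary topology
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1) + 0.01))
        parent.extend([left, right])
        nodes.append(parent)
    tree = nodes[0]
    tree.length = None  # root carries no branch

    n_unassigned = int(round(fraction_unassigned * n_taxa))
    unassigned = set(rng.choice(n_taxa, size=n_unassigned, replace=False).tolist())
    if n_genera is None:
        n_genera = max(2, (n_taxa - n_unassigned) // 2)
    lineages = []
    for i in range(n_taxa):
        if i in unassigned:
            lineages.append("k__Bacteria")
            continue
        g = int(rng.integers(n_genera))
        p = g % 5
        lineages.append(
            f"k__Bacteria; p__Phylum{p}; c__Class{p}; o__Order{g % 11}; "
            f"f__Family{g % 17}; g__Genus{g}; s__")
    taxonomy = pd.DataFrame({"feature_id": [f"t{i}" for i in range(n_taxa)],
                             "lineage": lineages})
    return tree, taxonomy


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def design_metadata(design: SimulationDesign) -> pd.DataFrame:
    """Deterministic sample metadata implied by a design (no randomness)."""
    rows = []
    for animal, group in design.animals():
        for day in design.sampling_days:
            rows.append({"sample_id": f"{animal}_d{day}",
                         "animal_id": animal,
                         "group": group,
                         "year": 1,
                         "day": int(day),
                         "phase": phase_of_day(day, design.perturbation_window)})
    return pd.DataFrame(rows)


def _se_kernel(days: np.ndarray, lengthscale: float, jitter: float = 1e-8) -> np.ndarray:
    d = np.subtract.outer(days, days)
    return np.exp(-0.5 * (d / lengthscale) ** 2) + jitter * np.eye(len(days))


def _perturbation_shift(design: SimulationDesign, truth: SyntheticTruth,
                        group: str, days: np.ndarray) -> np.ndarray:
    """Per-taxon x per-day log-abundance shift for a treated animal."""
    n, t = truth.n_taxa, len(days)
    shift = np.zeros((n, t))
    if group == "CON" or design.perturbation_effect == 0:
        return shift
    lo, hi = design.perturbation_window
    rate = design.recovery_rate_by_group.get(group, 0.0)
    amp = np.zeros(t)
    inside = (days >= lo) & (days <= hi)
    amp[inside] = 1.0
    after = days > hi
    if rate > 0:
        amp[after] = np.exp(-rate * (days[after] - hi))
    else:
        amp[after] = 1.0
    hit = np.setdiff1d(truth.perturbed_taxa, truth.resistant_taxa)
    susc = (truth.susceptibility if truth.susceptibility is not None
            else np.ones(n))
    shift[np.ix_(hit, np.arange(t))] = \
        -design.perturbation_effect * susc[hit, None] * amp[None, :]
    return shift


@dataclass
class SimulatedDataset:
    counts: CountTable
    metadata: pd.DataFrame
    latent_clr: dict[str, np.ndarray] | None = None  # animal -> taxa x days CLR


def simulate_counts(design: SimulationDesign, truth: SyntheticTruth,
                    export_latent: bool = False) -> SimulatedDataset:
    """Multinomial counts over latent Gaussian-process log-abundances.

    Per animal, latent log-abundance ``X`` (taxa x days) is matrix-normal
    with row covariance ``latent_sd^2 * true_correlation`` and column
    covariance a squared-exponential kernel over the sampling days; the
    treatment crash is subtracted from non-resistant perturbed taxa and
    decays at the group recovery rate; transfaunated animals are blended
    back toward their day -4 state from the transfaunation day onward.
    Counts per sample are multinomial at a depth drawn uniformly from
    ``depth_range``.
    """
    if truth.n_taxa != design.n_taxa:
        raise InvalidTruthError(
            f"truth has {truth.n_taxa} taxa but design expects {design.n_taxa}")
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.sampling_days, dtype=float)
    n, t = design.n_taxa, len(days)

    corr = truth.true_correlation
    eigmin = np.linalg.eigvalsh(corr).min()
    chol_r = np.linalg.cholesky(corr + max(0.0, 1e-10 - eigmin + 1e-12) * np.eye(n))
    chol_k = np.linalg.cholesky(_se_kernel(days, truth.true_lengthscale))
    baseline_mean = rng.normal(0.0, truth.baseline_logmean_sd, size=n)

    # nearest pretreatment day to -4 is the transfaunation source state
    pre = days[days < design.perturbation_window[0]]
    if pre.size:
        ft_source_col = int(np.argmin(np.abs(days - pre[np.argmin(np.abs(pre + 4))])))
    else:
        ft_source_col = 0

    meta = design_metadata(design)
    columns, sample_ids = [], []
    latents: dict[str, np.ndarray] = {}
    for animal, group in design.animals():
        z = rng.standard_normal((n, t))
        x = baseline_mean[:, None] + truth.latent_sd * (chol_r @ z @ chol_k.T)
        x = x + _perturbation_shift(design, truth, group, days)
        if group == "ABXFT" and design.transfaunation_weight > 0:
            w = design.transfaunation_weight
            post = days >= design.transfaunation_day
            x[:, post] = (1 - w) * x[:, post] + w * x[:, [ft_source_col]]
        if export_latent:
            latents[animal] = x - x.mean(axis=0, keepdims=True)
        logits = x - x.max(axis=0, keepdims=True)
        comp = np.exp(logits)
        comp /= comp.sum(axis=0, keepdims=True)
        for k, day in enumerate(days):
            depth = int(rng.integers(design.depth_range[0], design.depth_range[1] + 1))
            columns.append(rng.multinomial(depth, comp[:, k]))
            sample_ids.append(f"{animal}_d{int(day)}")
    values = np.column_stack(columns)
    counts = CountTable(values, [f"t{i}" for i in range(n)], sample_ids)
    return SimulatedDataset(counts=counts, metadata=meta,
                            latent_clr=latents if export_latent else None)


# ---------------------------------------------------------------------------
# resistome
# ---------------------------------------------------------------------------

def simulate_resistome(design: SimulationDesign, truth: SyntheticTruth,
                       n_genes: int = 83,
                       base_abr_fraction: float = 1e-3,
                       abr_enrichment: float = 2.0,
                       betalactam_enrichment: float = 3.0,
                       total_reads_range: tuple[int, int] = (800_000, 1_200_000),
                       ) -> tuple[ResistomeTable, pd.DataFrame]:
    """Antibiotic-resistance-gene counts correlated with treatment phase.

    Genes are partitioned over seven resistance families with a study-like
    baseline mix dominated by Tetracycline and Beta-lactam.  For treated
    animals, total ABR abundance is multiplied by ``abr_enrichment`` and the
    Beta-lactam family weight by ``betalactam_enrichment`` during the
    antibiotic window, decaying at the group recovery rate afterwards
    (enrichment factors of 1 give a null design).  Returns the gene table
    plus the shared sample metadata.
    """
    rng = np.random.default_rng(design.seed + 1_000_003)
    families = list(ABR_FAMILY_WEIGHTS)
    fam_w = np.array([ABR_FAMILY_WEIGHTS[f] for f in families])
    fam_w = fam_w / fam_w.sum()
    # allocate genes to families proportionally, at least one per family
    n_per_family = np.maximum(1, np.floor(fam_w * n_genes).astype(int))
    while n_per_family.sum() < n_genes:
        n_per_family[np.argmax(fam_w - n_per_family / n_genes)] += 1
    while n_per_family.sum() > n_genes:
        n_per_family[np.argmax(n_per_family)] -= 1
    gene_ids, gene_family, gene_w = [], [], []
    for f, k in zip(families, n_per_family):
        within = rng.dirichlet(np.full(k, 2.0))
        for g in range(k):
            gene_ids.append(f"{f.lower().replace('-', '')}_{g}")
            gene_family.append(f)
            gene_w.append(within[g])
    gene_w = np.array(gene_w)
    fam_idx = np.array([families.index(f) for f in gene_family])

    meta = design_metadata(design)
    lo, hi = design.perturbation_window
    cols, totals = [], []
    for _, row in meta.iterrows():
        day, group = row["day"], row["group"]
        treated = group in ("ABX", "ABXFT")
        rate = design.recovery_rate_by_group.get(group, 0.0)
        if treated and lo <= day <= hi:
            amp = 1.0
        elif treated and day > hi:
            amp = np.exp(-rate * (day - hi)) if rate > 0 else 1.0
        else:
            amp = 0.0
        fam_boost = np.ones(len(families))
        fam_boost[families.index("Beta-lactam")] = 1.0 + (betalactam_enrichment - 1.0) * amp
        w = fam_w * fam_boost
        w = w / w.sum()
        probs = gene_w * w[fam_idx]   # within-family weight x family weight
        probs = probs / probs.sum()
        total = int(rng.integers(total_reads_range[0], total_reads_range[1] + 1))
        frac = base_abr_fraction * (1.0 + (abr_enrichment - 1.0) * amp)
        abr_total = rng.binomial(total, frac)
        cols.append(rng.multinomial(abr_total, probs))
        totals.append(total)
    counts = pd.DataFrame(np.column_stack(cols), index=gene_ids,
                          columns=meta["sample_id"].tolist())
    table = ResistomeTable(counts=counts,
                           family=pd.Series(gene_family, index=gene_ids),
                           totals=pd.Series(totals, index=meta["sample_id"].tolist()))
    return table, meta
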