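"""Alpha diversity, phylogenetic beta diversity, distance-from-baseline
series, ordination, and the baseline group test.

Unweighted UniFrac is computed from the rooted tree by an edge-presence
matrix: a branch "belongs" to a sample when any descendant leaf is present
(count > 0); the distance is unshared branch length over the branch length
in either sample's spanned set.  A normalized weighted variant is exposed
as a secondary metric.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .tables import CountTable

logger = logging.getLogger(__name__)


def shannon(table: CountTable, log_base: float = 2.0) -> pd.Series:
    """Shannon-Weaver diversity H = -sum p_i log(p_i) per sample.

    Defaults to log base 2 (bits); base e gives the classical nat-scale
    index.  The base used is recorded in the Series name.
    """
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"Shannon diversity undefined for empty samples: {empty}")
    p = table.values / sums
    logp = np.log(np.where(p > 0, p, 1.0))  # p log p -> 0 at p == 0
    h = -(p * logp).sum(axis=0) / np.log(log_base)
    return pd.Series(h, index=table.sample_ids, name=f"shannon_base{log_base:g}")


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _edge_presence(table: CountTable, tree: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-edge x per-sample presence indicators."""
    leaf_names = {leaf.name for leaf in tree.tips()}
    nonzero = table.values.sum(axis=1) > 0
    missing = [t for t, nz in zip(table.taxon_ids, nonzero) if nz and t not in leaf_names]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")
    row_of = {t: i for i, t in enumerate(table.taxon_ids)}
    present = table.values > 0  # taxa x samples
    n_samples = table.n_samples

    lengths: list[float] = []
    rows: list[np.ndarray] = []
    node_presence: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = row_of.get(node.name)
            p = present[i] if i is not None else np.zeros(n_samples, dtype=bool)
        else:
            p = np.zeros(n_samples, dtype=bool)
            for child in node.children:
                p = p | node_presence[id(child)]
        node_presence[id(node)] = p
        if node.parent is not None:  # root carries no branch
            lengths.append(float(node.length or 0.0))
            rows.append(p)
    return np.asarray(lengths), np.asarray(rows)


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Pairwise unweighted UniFrac over the table's samples.

    distance(a, b) = branch length unique to one sample's spanned set over
    branch length in the union of both sets; two samples with identical
    presence profiles (including two empty samples) are at distance 0.
    """
    lengths, presence = _edge_presence(table, tree)
    pf = presence.astype(float)
    weighted = lengths[:, None] * pf                 # edges x samples
    total = weighted.sum(axis=0)                     # branch length per sample
    both = pf.T @ weighted                           # shared branch length
    union = total[:, None] + total[None, :] - both
    unique = total[:, None] + total[None, :] - 2 * both
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(union > 0, unique / union, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, ids=table.sample_ids)


def weighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Normalized weighted UniFrac (secondary metric): branch lengths
    weighted by the absolute difference in descendant relative abundance,
    normalized by the abundance-weighted total."""
    lengths, _ = _edge_presence(table, tree)
    # recompute per-edge relative-abundance mass (not just presence)
    row_of = {t: i for i, t in enumerate(table.taxon_ids)}
    sums = table.sample_sums().astype(float)
    rel = np.divide(table.values, np.where(sums == 0, 1.0, sums))
    masses: list[np.ndarray] = []
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = row_of.get(node.name)
            m = rel[i].astype(float) if i is not None else np.zeros(table.n_samples)
        else:
            m = np.zeros(table.n_samples)
            for child in node.children:
                m = m + node_mass[id(child)]
        node_mass[id(node)] = m
        if node.parent is not None:
            masses.append(m)
    mass = np.asarray(masses)
    diff = np.abs(mass[:, :, None] - mass[:, None, :])
    tot = mass[:, :, None] + mass[:, None, :]
    num = np.einsum("e,eab->ab", lengths, diff)
    den = np.einsum("e,eab->ab", lengths, tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(den > 0, num / den, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# distance from baseline
# ---------------------------------------------------------------------------

def distance_from_baseline(dm: DistanceMatrix, metadata: pd.DataFrame,
                           baseline_day: int = -4) -> pd.DataFrame:
    """Per-sample distance to the same animal's baseline community.

    The baseline is the animal's sample at ``baseline_day`` (day -4 by
    default, the transfaunation-source collection); when that day is
    missing, the nearest pretreatment sample is used (logged).  Animals
    without any pretreatment sample are excluded with a warning.
    """
    ids = set(dm.ids)
    md = metadata[metadata["sample_id"].isin(ids)]
    rows = []
    for animal, sub in md.groupby("animal_id"):
        pre = sub[sub["day"] < 0]
        if pre.empty:
            warnings.warn(f"animal {animal} has no pretreatment sample; excluded",
                          UserWarning, stacklevel=2)
            continue
        at = pre[pre["day"] == baseline_day]
        if len(at):
            base = at.iloc[0]
        else:
            base = pre.iloc[(pre["day"] - baseline_day).abs().argmin()]
            logger.info("animal %s: no day %d sample, baseline falls back to day %d",
                        animal, baseline_day, base["day"])
        for _, r in sub.iterrows():
            rows.append({"sample_id": r["sample_id"], "animal_id": animal,
                         "group": r["group"], "day": r["day"], "phase": r["phase"],
                         "baseline_sample": base["sample_id"],
                         "distance": float(dm[r["sample_id"], base["sample_id"]])})
    columns = ["sample_id", "animal_id", "group", "day", "phase",
               "baseline_sample", "distance"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows).sort_values(["animal_id", "day"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ordination & baseline test
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResults:
    """Classical multidimensional scaling (principal coordinates) of a
    distance matrix; returns the top-``k`` components (fewer, with a
    warning, when the positive-eigenvalue rank is below ``k``)."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*negative eigenvalues.*")
        warnings.filterwarnings("ignore", message=".*no value for dimensions.*")
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    positive = int((res.eigvals > 1e-10).sum())
    avail = min(k, positive) if positive else min(k, res.samples.shape[1])
    if avail < k:
        warnings.warn(f"only {avail} positive components available (requested {k})",
                      UserWarning, stacklevel=2)
    res.samples = res.samples.iloc[:, :avail]
    res.eigvals = res.eigvals.iloc[:avail]
    return res


def kruskal_wallis_groups(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis rank test of a per-sample quantity across groups
    (tie-corrected H, chi-square p with g-1 df)."""
    values, groups = pd.Series(values), pd.Series(groups)
    samples = [values[groups == g].to_numpy() for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if all(np.ptp(np.concatenate(samples)) == 0 for _ in (0,)):
        return 0.0, 1.0  # full ties: H = 0 by convention
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
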