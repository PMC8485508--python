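"""Feature-table filters, rarefaction, taxonomic collapsing, and
compositional transforms.

Boundary semantics follow the study protocol literally: samples with fewer
than 10,000 reads are discarded (>= keeps), taxa present in fewer than five
samples are removed, and genera holding less than 0.01% of total counts are
folded into "Other".  Sequencing-count uncertainty is propagated by
Dirichlet Monte-Carlo resampling (ALDEx2-style, Jeffreys-like prior 0.5 per
cell) followed by the centered log-ratio transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable

logger = logging.getLogger(__name__)

RANKS = ("k", "p", "c", "o", "f", "g", "s")


# ---------------------------------------------------------------------------
# sample / taxon filters
# ---------------------------------------------------------------------------

def filter_samples(table: CountTable, min_reads: int = 10_000) -> CountTable:
    """Keep samples whose total count is at least ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return table.select_samples(table.sample_sums() >= min_reads)


def rarefy(table: CountTable, depth: int = 15_000,
           seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample every sample without replacement to a common depth.

    Samples with fewer than ``depth`` reads are dropped; each retained
    column is a uniform without-replacement (multivariate hypergeometric)
    subsample summing exactly to ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sums = table.sample_sums()
    kept = table.select_samples(sums >= depth)
    out = np.empty_like(kept.values)
    for j in range(kept.n_samples):
        col = kept.values[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(out, list(kept.taxon_ids), list(kept.sample_ids))


def filter_rare_taxa(table: CountTable, min_samples: int = 5) -> CountTable:
    """Drop taxa with nonzero counts in fewer than ``min_samples`` samples."""
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    prevalence = (table.values > 0).sum(axis=1)
    return table.select_taxa(prevalence >= min_samples)


# ---------------------------------------------------------------------------
# taxonomy collapsing and low-abundance grouping
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a QIIME2-style semicolon lineage into rank -> label (resolved
    ranks only; empty labels like ``s__`` are unresolved)."""
    out: dict[str, str] = {}
    for part in str(lineage).split(";"):
        part = part.strip()
        if len(part) >= 3 and part[1:3] == "__" and part[0] in RANKS and part[3:]:
            out[part[0]] = part[3:]
    return out


def genus_label(lineage: str) -> str:
    """Genus-level label for one lineage; features unresolved at genus get
    their deepest resolved rank label suffixed "(unresolved)"."""
    ranks = parse_lineage(lineage)
    if "g" in ranks:
        return f"g__{ranks['g']}"
    for r in reversed(RANKS[:-2]):  # deepest resolved rank above genus
        if r in ranks:
            return f"{r}__{ranks[r]} (unresolved)"
    return "Unassigned (unresolved)"


def collapse_genus(table: CountTable, taxonomy: pd.DataFrame | pd.Series) -> CountTable:
    """Sum feature rows sharing a genus label; total count is conserved.

    ``taxonomy`` is either a two-column frame (``feature_id``, ``lineage``)
    or a Series mapping feature id -> lineage.  Every taxon in the table
    must have a lineage entry.
    """
    if isinstance(taxonomy, pd.DataFrame):
        lineages = taxonomy.set_index("feature_id")["lineage"]
    else:
        lineages = taxonomy
    missing = [t for t in table.taxon_ids if t not in lineages.index]
    if missing:
        raise ValueError(f"taxa without a lineage entry: {missing}")
    labels = [genus_label(lineages.loc[t]) for t in table.taxon_ids]
    frame = table.to_frame().groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    return CountTable.from_frame(frame)


def group_other_taxa(table: CountTable, min_total_frac: float = 1e-4) -> CountTable:
    """Fold taxa holding < ``min_total_frac`` of grand-total counts into a
    single "Other" row; logs the fraction of counts moved."""
    if not 0 <= min_total_frac < 1:
        raise ValueError("min_total_frac must lie in [0, 1)")
    grand = table.values.sum()
    if grand == 0:
        return table.copy()
    share = table.taxon_sums() / grand
    low = share < min_total_frac
    moved = table.values[low].sum() / grand
    logger.info("group_other_taxa: folded %d taxa holding %.4f%% of counts into 'Other'",
                int(low.sum()), 100 * moved)
    if not low.any():
        return table.copy()
    frame = table.to_frame()
    other = frame.loc[low].sum(axis=0)
    frame = frame.loc[~low]
    if "Other" in frame.index:
        frame.loc["Other"] += other
    else:
        frame.loc["Other"] = other
    return CountTable.from_frame(frame)


# ---------------------------------------------------------------------------
# compositional transforms
# ---------------------------------------------------------------------------

def clr_transform(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio: log(x) minus the per-column mean log.

    Columns are compositions (taxa down the rows); output columns sum to
    zero.  Inputs must be strictly positive — zeros are handled upstream by
    Dirichlet resampling, never here.
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("clr_transform requires strictly positive inputs")
    logx = np.log(x)
    return logx - logx.mean(axis=0, keepdims=True)


@dataclass
class ClrInstance:
    """One Dirichlet-resampled, CLR-transformed matrix for one animal's
    series (taxa x timepoints; columns sum to zero)."""

    values: np.ndarray
    days: np.ndarray
    animal_id: str = ""
    instance_index: int = 0
    taxon_ids: list[str] | None = None
    #: relax the zero-sum column check for non-compositional latent series
    enforce_closure: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.days = np.asarray(self.days, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.days):
            raise ValueError("values must be taxa x timepoints matching days")
        if not (np.diff(self.days) > 0).all():
            raise ValueError("days must be strictly increasing")
        if self.enforce_closure and np.abs(self.values.sum(axis=0)).max() > 1e-9:
            raise ValueError("CLR columns must sum to zero")


def dirichlet_instances(series: CountTable, days: np.ndarray,
                        n_instances: int = 128, prior: float = 0.5,
                        seed: int | np.random.Generator = 0,
                        animal_id: str = "") -> list[ClrInstance]:
    """Dirichlet Monte-Carlo CLR instances for one animal's count series.

    For each instance and timepoint, draws a composition from
    Dirichlet(counts + prior) and CLR-transforms it, emulating the
    variation expected from replicate measurements of the same community.
    """
    if series.n_samples == 0:
        raise ValueError("empty series")
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if prior <= 0:
        raise ValueError("prior must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    alpha = series.values.astype(float) + prior  # taxa x timepoints
    d, t = alpha.shape
    out = []
    for i in range(n_instances):
        # gamma trick: column-wise Dirichlet draws in one shot
        g = rng.gamma(shape=alpha)
        comp = g / g.sum(axis=0, keepdims=True)
        out.append(ClrInstance(values=clr_transform(comp), days=np.asarray(days, float),
                               animal_id=animal_id, instance_index=i,
                               taxon_ids=list(series.taxon_ids)))
    return out


# ---------------------------------------------------------------------------
# association-analysis prefilter
# ---------------------------------------------------------------------------

def association_prefilter(table: CountTable, metadata: pd.DataFrame,
                          taxonomy: pd.DataFrame | pd.Series,
                          min_samples: int = 5, min_total_frac: float = 1e-4,
                          ) -> tuple[CountTable, pd.DataFrame, dict]:
    """Study-order prefilter for the covariation analysis: drop pretreatment
    samples, remove rare taxa, collapse to genus, fold low-abundance genera
    into "Other".  Returns the filtered table, matching metadata, and a log
    of counts removed at each step."""
    md = metadata[metadata["sample_id"].isin(table.sample_ids)]
    keep_samples = md.loc[md["phase"] != "pretreatment", "sample_id"].tolist()
    log: dict[str, float] = {"input_total": float(table.values.sum())}
    t1 = table.select_samples(keep_samples)
    log["after_drop_pretreatment"] = float(t1.values.sum())
    t2 = filter_rare_taxa(t1, min_samples)
    log["after_filter_rare_taxa"] = float(t2.values.sum())
    t3 = collapse_genus(t2, taxonomy)
    log["after_collapse_genus"] = float(t3.values.sum())
    t4 = group_other_taxa(t3, min_total_frac)
    log["after_group_other"] = float(t4.values.sum())
    log["fraction_removed"] = 1.0 - log["after_group_other"] / max(log["after_drop_pretreatment"], 1.0)
    md_out = md[md["sample_id"].isin(t4.sample_ids)].reset_index(drop=True)
    return t4, md_out, log


def animal_series(table: CountTable, metadata: pd.DataFrame,
                  animal_id: str) -> tuple[CountTable, np.ndarray]:
    """One animal's count series ordered by day (table columns + days)."""
    md = metadata[metadata["sample_id"].isin(table.sample_ids)]
    sub = md[md["animal_id"] == animal_id].sort_values("day")
    if sub.empty:
        raise ValueError(f"no samples for animal {animal_id}")
    return table.select_samples(sub["sample_id"].tolist()), sub["day"].to_numpy(float)
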