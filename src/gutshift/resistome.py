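"""Antibiotic-resistance-gene (resistome) summaries.

Cross-sectional summaries relate per-animal ABR gene load to lifetime
antibiotic exposure; longitudinal summaries track ABR relative abundance
and resistance-family proportions per experimental group and day.  The
underlying shotgun counts are small-n, so the study-style analysis is
descriptive (means +/- SEM, qualitative trend classification); the
permutation Spearman test offered here is a quantitative extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ABR_FAMILIES = ("Tetracycline", "Beta-lactam", "Aminoglycoside", "Macrolide",
                "Vancomycin", "MDR", "Sulphonamide", "Other")


@dataclass
class ResistomeTable:
    """Gene x sample ABR counts with a gene->family map and per-sample
    total sequenced reads (the relative-abundance denominator)."""

    counts: pd.DataFrame            # genes x samples, non-negative ints
    family: pd.Series               # gene -> family
    totals: pd.Series               # sample -> total reads

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("ABR counts must be non-negative")
        missing = self.counts.index.difference(self.family.index)
        if len(missing):
            raise ValueError(f"genes without a family mapping: {list(missing)}")
        self.family = self.family.reindex(self.counts.index)
        unknown = set(self.family) - set(ABR_FAMILIES)
        if unknown:  # families outside the named set collapse to Other
            self.family = self.family.where(~self.family.isin(unknown), "Other")
        missing_tot = self.counts.columns.difference(self.totals.index)
        if len(missing_tot):
            raise ValueError(f"samples without total read counts: {list(missing_tot)}")
        self.totals = self.totals.reindex(self.counts.columns)
        gene_sums = self.counts.sum(axis=0)
        short = self.totals[self.totals < gene_sums]
        if len(short):
            raise ValueError(
                f"total reads below summed gene counts for samples {list(short.index)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def family_counts(self) -> pd.DataFrame:
        """Family x sample counts (genes summed within family)."""
        return self.counts.groupby(self.family).sum()


def family_proportions(table: ResistomeTable) -> pd.DataFrame:
    """Per-sample fractions over resistance-gene families (rows: samples).

    Samples with zero ABR reads yield an all-zero row with a warning.
    """
    fam = table.family_counts().T  # samples x families
    sums = fam.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"samples with zero ABR reads: {list(fam.index[zero])}",
                      UserWarning, stacklevel=2)
    out = fam.div(sums.where(~zero, 1.0), axis=0)
    out[zero] = 0.0
    return out


def abr_relative_abundance(table: ResistomeTable) -> pd.Series:
    """Summed ABR gene counts over total sequenced reads, per sample."""
    if table.totals.isna().any() or (table.totals <= 0).any():
        bad = list(table.totals.index[table.totals.isna() | (table.totals <= 0)])
        raise ValueError(f"missing or non-positive total reads for {bad}")
    return table.counts.sum(axis=0) / table.totals


def _classify_trend(pre: float, treat: float, rec: float, tol: float = 0.0) -> str:
    up = treat > pre + tol
    down = rec < treat - tol
    if up and down:
        return "up-then-down"
    if up:
        return "up"
    if treat < pre - tol and rec > treat + tol:
        return "down-then-up"
    if treat < pre - tol:
        return "down"
    return "flat"


def longitudinal_summary(table: ResistomeTable, metadata: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x day mean +/- SEM of ABR relative abundance and of each
    family proportion, plus a per-group phase-trend classification.

    SEM is over animals within a (group, day) cell; single-animal cells get
    a missing SEM.  The trend classifies the pre -> treatment -> recovery
    direction of phase-mean ABR relative abundance (e.g. "up-then-down").
    """
    md = metadata.set_index("sample_id")
    rel = abr_relative_abundance(table).rename("abr_relabund")
    fam = family_proportions(table)
    long = fam.join(rel).join(md[["animal_id", "group", "day", "phase"]])

    value_cols = [c for c in long.columns if c not in ("animal_id", "group", "day", "phase")]
    per_animal = long.groupby(["group", "day", "animal_id"])[value_cols].mean()
    grouped = per_animal.groupby(["group", "day"])
    mean = grouped.mean()
    n = grouped.size()
    sem = grouped.std(ddof=1).div(np.sqrt(n), axis=0)  # NaN when n == 1
    summary = pd.concat({"mean": mean, "sem": sem}, axis=1)
    summary["n_animals"] = n

    phase_means = long.groupby(["group", "phase"])["abr_relabund"].mean().unstack()
    trends = []
    for g in phase_means.index:
        row = phase_means.loc[g]
        pre = row.get("pretreatment", np.nan)
        # 5% relative tolerance so sampling wobble is not called a trend
        tol = 0.05 * pre if np.isfinite(pre) else 0.0
        trends.append({
            "group": g,
            "pretreatment": pre,
            "treatment": row.get("treatment", np.nan),
            "recovery": row.get("recovery", np.nan),
            "trend": _classify_trend(pre, row.get("treatment", np.nan),
                                     row.get("recovery", np.nan), tol=tol),
        })
    return summary, pd.DataFrame(trends)


def cross_sectional_summary(table: ResistomeTable, exposure: pd.Series,
                            metadata: pd.DataFrame | None = None,
                            n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Per-animal ABR load versus lifetime antibiotic exposure.

    ``exposure`` maps animal id -> number of lifetime antibiotic courses.
    Returns one row per animal (mean ABR relative abundance over that
    animal's samples, exposure, rank) with Spearman rho and a permutation
    p-value attached as frame attrs; rho is NA when exposure has no
    variation.
    """
    rel = abr_relative_abundance(table)
    if metadata is not None:
        animal_of = metadata.set_index("sample_id")["animal_id"]
        per_animal = rel.groupby(animal_of.reindex(rel.index)).mean()
    else:
        per_animal = rel.copy()
        per_animal.index.name = "animal_id"
    missing = per_animal.index.difference(exposure.index)
    if len(missing):
        raise ValueError(f"exposure unknown for animals: {list(missing)}")
    exposure = exposure.reindex(per_animal.index).astype(float)

    out = pd.DataFrame({"abr_relabund": per_animal, "exposure": exposure})
    out = out.sort_values("exposure")
    if exposure.nunique() < 2:
        rho, p = np.nan, np.nan
    else:
        rho = stats.spearmanr(out["exposure"], out["abr_relabund"]).statistic
        rng = np.random.default_rng(seed)
        vals = out["abr_relabund"].to_numpy()
        perm_rhos = np.array([
            stats.spearmanr(out["exposure"], rng.permutation(vals)).statistic
            for _ in range(n_perm)])
        p = (1 + np.sum(np.abs(perm_rhos) >= abs(rho) - 1e-12)) / (1 + n_perm)
    out.attrs["spearman_rho"] = rho
    out.attrs["permutation_p"] = p
    return out
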