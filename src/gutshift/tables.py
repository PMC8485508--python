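"""Core containers for taxa-by-sample count data and sample metadata.

The count table is the universal currency between pipeline stages: a dense
non-negative integer matrix with taxon rows and sample columns.  Sample
metadata travels as a plain :class:`pandas.DataFrame` with the columns
``sample_id, animal_id, group, year, day, phase``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("CON", "ABX", "ABXFT")
PHASES = ("pretreatment", "treatment", "recovery")

#: treatment window in study days, inclusive; day 7 (transfaunation) is recovery
TREATMENT_WINDOW = (0, 6)


class EmptyTableWarning(UserWarning):
    """A filtering step removed every sample (or taxon)."""


def phase_of_day(day: int | float,
                 window: tuple[int, int] = TREATMENT_WINDOW) -> str:
    """Study phase for a sampling day: pretreatment < day 0, treatment days
    0..6 inclusive, recovery afterwards (transfaunation day 7 is recovery)."""
    lo, hi = window
    if day < lo:
        return "pretreatment"
    if day <= hi:
        return "treatment"
    return "recovery"


@dataclass
class CountTable:
    """Taxa x samples non-negative integer count matrix.

    Parameters
    ----------
    values : ndarray of shape (n_taxa, n_samples)
        Integer counts.
    taxon_ids, sample_ids : sequences of str
        Unique row / column identifiers.
    """

    values: np.ndarray
    taxon_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D taxa x samples matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded):
                raise ValueError("count table cells must be integers")
            self.values = rounded.astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at taxon {i} ({self.taxon_ids[i] if self.taxon_ids else '?'}), "
                f"sample {j} ({self.sample_ids[j] if self.sample_ids else '?'})")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.taxon_ids) != self.values.shape[0]:
            raise ValueError("taxon_ids length does not match values rows")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match values columns")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    # -- basic views ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.taxon_ids, name="taxon_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    # -- selection -----------------------------------------------------
    def select_samples(self, keep: np.ndarray | list) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        out = CountTable(self.values[:, idx],
                         list(self.taxon_ids),
                         [self.sample_ids[i] for i in idx])
        if out.n_samples == 0:
            warnings.warn("all samples removed", EmptyTableWarning, stacklevel=2)
        return out

    def select_taxa(self, keep: np.ndarray | list) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {t: i for i, t in enumerate(self.taxon_ids)}
            idx = np.array([pos[t] for t in keep], dtype=int)
        out = CountTable(self.values[idx, :],
                         [self.taxon_ids[i] for i in idx],
                         list(self.sample_ids))
        if out.n_taxa == 0:
            warnings.warn("all taxa removed", EmptyTableWarning, stacklevel=2)
        return out

    def copy(self) -> "CountTable":
        return CountTable(self.values.copy(), list(self.taxon_ids), list(self.sample_ids))

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, CountTable):
            return NotImplemented
        return (self.taxon_ids == other.taxon_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values))


def validate_metadata(metadata: pd.DataFrame,
                      treatment_window: tuple[int, int] = TREATMENT_WINDOW) -> pd.DataFrame:
    """Validate and complete a sample-metadata frame.

    Requires ``sample_id, animal_id, group, day``; derives ``phase`` from
    ``day`` when absent and fills ``year`` with 1.
    """
    required = ["sample_id", "animal_id", "group", "day"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    md = metadata.copy()
    bad = sorted(set(md["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels {bad}; expected one of {GROUPS}")
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    if "phase" not in md.columns:
        md["phase"] = [phase_of_day(d, treatment_window) for d in md["day"]]
    if "year" not in md.columns:
        md["year"] = 1
    return md
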