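"""Readers and writers for the pipeline's external formats.

Count tables travel as TSV (taxa rows x sample columns, header of sample
ids) or BIOM (JSON dialect); metadata and taxonomy as TSV; trees as
Newick; distance matrices as symmetric TSV with an id header
(QIIME2-compatible).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .tables import CountTable, validate_metadata

FLOAT_FORMAT = "%.10g"


def load_feature_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a taxa x samples integer count table (TSV or BIOM)."""
    path = Path(path)
    if format == "biom":
        import biom
        table = biom.load_table(str(path))
        frame = table.to_dataframe(dense=True)
        frame.index.name = "taxon_id"
        return CountTable.from_frame(frame)
    if format != "tsv":
        raise ValueError(f"unknown feature-table format {format!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        raise ValueError(f"duplicate taxon ids: {frame.index[frame.index.duplicated()].tolist()}")
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce")
        if bad.isna().any():
            row = frame.index[bad.isna().argmax()]
            raise ValueError(f"non-numeric cell at taxon {row!r}, sample {col!r}")
    values = frame.to_numpy()
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"negative count at taxon {frame.index[i]!r}, "
                         f"sample {frame.columns[j]!r}")
    return CountTable.from_frame(frame)


def write_feature_table(table: CountTable, path: str | Path,
                        format: str = "tsv") -> None:
    path = Path(path)
    if format == "biom":
        import biom
        bt = biom.Table(table.values, observation_ids=table.taxon_ids,
                        sample_ids=table.sample_ids)
        path.write_text(bt.to_json(generated_by="gutshift"))
        return
    if format != "tsv":
        raise ValueError(f"unknown feature-table format {format!r}")
    table.to_frame().to_csv(path, sep="\t")


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV; derives phase from day when absent and
    validates group labels."""
    md = pd.read_csv(path, sep="\t")
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    """Two-column taxonomy TSV (feature id, semicolon-delimited lineage)."""
    tax = pd.read_csv(path, sep="\t")
    tax.columns = ["feature_id", "lineage"] + list(tax.columns[2:])
    return tax[["feature_id", "lineage"]]


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False)


def load_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def load_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=list(frame.columns))


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def edges_to_graphml(edges: pd.DataFrame, path: str | Path,
                     strong_only: bool = True) -> None:
    """Export an association edge table for network tools."""
    import networkx as nx
    g = nx.Graph()
    sub = edges[edges["strong"]] if strong_only else edges
    for r in sub.itertuples():
        g.add_edge(r.taxon_i, r.taxon_j, rho=float(r.rho_median),
                   sign=int(r.sign), significant=bool(r.significant))
    nx.write_graphml(g, str(path))
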