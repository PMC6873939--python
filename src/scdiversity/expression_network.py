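"""Cluster mean-expression profiles and the cluster distance network.

Each cluster is summarised by the per-gene geometric mean of UMI counts over
its cells, computed with a pseudocount so that zeros are defined:

    profile_g = exp( mean_cells ln(count + c) ) - c

with c > 0 (default 1).  An all-zero gene stays exactly 0 for any c, and as
c -> 0 the value tends to the plain geometric mean when all counts are
positive.  Pairwise Euclidean distances between profile vectors define a
metric on clusters, and the resulting complete graph — nodes carrying
cluster size and condition composition, edges carrying distance — shows
whether clusters segregate by condition in mean expression space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from .cluster_compare import CellAnnotationTable

__all__ = [
    "ClusterExpressionProfile",
    "ExpressionMatrix",
    "build_cluster_graph",
    "cluster_distance_matrix",
    "cluster_profiles",
    "write_graph_tables",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Sparse genes x cells UMI count matrix with identifier lists."""

    gene_ids: tuple
    barcodes: tuple
    counts: sp.csc_matrix

    def __post_init__(self) -> None:
        counts = sp.csc_matrix(self.counts)
        n_genes, n_cells = counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but matrix has {n_genes} rows"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"{len(self.barcodes)} barcodes but matrix has {n_cells} columns"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("UMI counts must be non-negative")
        if counts.nnz and np.any(counts.data != np.floor(counts.data)):
            raise ValueError("UMI counts must be integral")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class ClusterExpressionProfile:
    """Per-gene geometric-mean expression of one cluster."""

    cluster_id: int
    values: np.ndarray
    n_cells: int


def cluster_profiles(
    matrix: ExpressionMatrix,
    table: CellAnnotationTable,
    pseudocount: float = 1.0,
    normalize: bool = False,
) -> list[ClusterExpressionProfile]:
    """Geometric-mean expression profile for every cluster in ``table``.

    Cells of a cluster are pooled regardless of sample of origin.  With
    ``normalize=True`` each cell's counts are first scaled to the median
    per-cell total (a counts-per-total adjustment); the default leaves raw
    counts untouched.

    Raises a consistency error if any annotated barcode is absent from the
    matrix.  Empty clusters cannot arise from a valid annotation table.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    col_of = {bc: j for j, bc in enumerate(matrix.barcodes)}
    missing = [bc for bc in table.df["barcode"] if bc not in col_of]
    if missing:
        raise ValueError(
            f"{len(missing)} annotated barcodes absent from the expression "
            f"matrix, e.g. {missing[:5]}"
        )
    counts = matrix.counts.astype(float)
    if normalize:
        totals = np.asarray(counts.sum(axis=0)).ravel()
        if np.any(totals == 0):
            warnings.warn("cells with zero total counts left unscaled")
        scale = np.divide(
            np.median(totals[totals > 0]), totals,
            out=np.ones_like(totals), where=totals > 0,
        )
        counts = counts @ sp.diags(scale)
    counts = sp.csc_matrix(counts)
    log_pc = np.log(pseudocount)
    profiles = []
    for cid, rows in table.df.groupby("cluster"):
        cols = np.array([col_of[bc] for bc in rows["barcode"]])
        sub = counts[:, cols]
        n = cols.size
        # mean of ln(count + c): nonzero entries explicitly, zeros contribute ln(c)
        log_sub = sub.copy()
        log_sub.data = np.log(log_sub.data + pseudocount)
        nnz_per_gene = np.diff(sub.tocsr().indptr)
        mean_log = (
            np.asarray(log_sub.sum(axis=1)).ravel() + (n - nnz_per_gene) * log_pc
        ) / n
        values = np.exp(mean_log) - pseudocount
        values[values < 0] = 0.0  # guard fp round-off at all-zero genes
        profiles.append(
            ClusterExpressionProfile(int(cid), values, int(n))
        )
    return profiles


def cluster_distance_matrix(
    profiles: list[ClusterExpressionProfile],
) -> pd.DataFrame:
    """Pairwise Euclidean distances between cluster profiles.

    All profiles must share gene order (they do when produced by
    :func:`cluster_profiles` from one matrix).  Returns a symmetric frame
    indexed by cluster id with zero diagonal.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 cluster profiles")
    lengths = {p.values.shape[0] for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have inconsistent gene counts: {sorted(lengths)}")
    ids = [p.cluster_id for p in profiles]
    stacked = np.vstack([p.values for p in profiles])
    mat = squareform(pdist(stacked, metric="euclidean"))
    return pd.DataFrame(mat, index=ids, columns=ids)


def build_cluster_graph(
    distmat: pd.DataFrame,
    table: CellAnnotationTable,
    layout_epsilon: float = 1e-6,
) -> nx.Graph:
    """Condition-annotated complete graph over clusters.

    Nodes carry ``size`` (cell total), ``condition_composition`` (proportion
    of the cluster's cells per condition, summing to 1) and
    ``majority_condition`` (ties broken toward the lexicographically smallest
    label).  Edges carry the raw Euclidean ``distance`` plus a
    ``layout_weight`` of 1/(distance + epsilon) usable by force-directed
    layouts, where similar clusters attract.
    """
    graph_clusters = set(distmat.index)
    table_clusters = set(table.cluster_space)
    if graph_clusters != table_clusters:
        raise ValueError(
            "cluster sets disagree: distance matrix has "
            f"{sorted(graph_clusters)}, table has {sorted(table_clusters)}"
        )
    g = nx.Graph()
    for cid, rows in table.df.groupby("cluster"):
        comp = rows["condition"].value_counts(normalize=True).sort_index()
        majority = comp[comp == comp.max()].index.min()
        g.add_node(
            int(cid),
            size=int(len(rows)),
            condition_composition={str(k): float(v) for k, v in comp.items()},
            majority_condition=str(majority),
        )
    for i, a in enumerate(distmat.index):
        for b in distmat.index[i + 1 :]:
            d = float(distmat.loc[a, b])
            g.add_edge(int(a), int(b), distance=d, layout_weight=1.0 / (d + layout_epsilon))
    return g


def write_graph_tables(graph: nx.Graph, outdir) -> tuple[Path, Path]:
    """Emit ``nodes.csv`` and ``edges.csv`` for a cluster graph."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = sorted(
        {c for _, d in graph.nodes(data=True) for c in d["condition_composition"]}
    )
    node_rows = []
    for n, d in sorted(graph.nodes(data=True)):
        row = {
            "cluster": n,
            "size": d["size"],
            "majority_condition": d["majority_condition"],
        }
        for c in conditions:
            row[f"prop_{c}"] = d["condition_composition"].get(c, 0.0)
        node_rows.append(row)
    edge_rows = [
        {"cluster_a": a, "cluster_b": b, "distance": d["distance"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    nodes_path = outdir / "nodes.csv"
    edges_path = outdir / "edges.csv"
    pd.DataFrame(node_rows).to_csv(nodes_path, index=False)
    pd.DataFrame(edge_rows).to_csv(edges_path, index=False)
    return nodes_path, edges_path
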