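"""Occupancy distributions over a joint cluster space and their KS comparison.

All samples are assumed to have been clustered *together*, so every sample's
composition lives on the same ordered set of cluster identifiers (possibly
with zero occupancy in some samples).  Samples or pooled conditions are then
compared with the Kolmogorov-Smirnov distance between their discrete
occupancy mass functions: the maximum absolute difference between the two
cumulative distributions accumulated along the canonical (ascending
cluster-id) order.  Because the clusters are categorical, the KS value
depends on that ordering; fixing it to the ascending joint-clustering order
makes results deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_diversity import ClusterDistribution

__all__ = [
    "AlignmentError",
    "CellAnnotationTable",
    "ks_distance",
    "occupancy",
    "pairwise_ks",
]

REQUIRED_COLUMNS = ("barcode", "sample_id", "condition", "cluster")


class AlignmentError(ValueError):
    """Raised when two distributions are not on the same cluster space."""


@dataclass(frozen=True)
class CellAnnotationTable:
    """One row per cell: barcode, sample of origin, condition, cluster label.

    The underlying frame is validated on construction: barcodes must be
    unique, sample/condition fields non-empty, and cluster labels integral.
    The cluster space of the table is the sorted set of observed cluster ids;
    it is shared across samples because clustering was joint.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("annotation table is empty")
        if df["barcode"].duplicated().any():
            dupes = df.loc[df["barcode"].duplicated(), "barcode"].head(5).tolist()
            raise ValueError(f"duplicate barcodes, e.g. {dupes}")
        for col in ("sample_id", "condition"):
            vals = df[col]
            if vals.isna().any() or (vals.astype(str).str.len() == 0).any():
                raise ValueError(f"column {col!r} has empty entries")
        clusters = df["cluster"]
        if clusters.isna().any():
            raise ValueError("column 'cluster' has missing entries")
        as_int = pd.to_numeric(clusters, errors="coerce")
        if as_int.isna().any() or not (as_int == np.floor(as_int)).all():
            raise ValueError("cluster labels must be integers")
        if (as_int < 0).any():
            raise ValueError("cluster labels must be non-negative")
        df = df.assign(cluster=as_int.astype(np.int64)).reset_index(drop=True)
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cluster_space(self) -> tuple:
        """Sorted distinct cluster ids — the canonical joint cluster order."""
        return tuple(sorted(self.df["cluster"].unique()))

    @property
    def sample_ids(self) -> tuple:
        return tuple(sorted(self.df["sample_id"].unique()))

    @property
    def conditions(self) -> tuple:
        return tuple(sorted(self.df["condition"].unique()))

    def subset(self, row_indices) -> "CellAnnotationTable":
        """Positional row subset (used by the downsampling protocol)."""
        sub = self.df.iloc[np.asarray(row_indices)].reset_index(drop=True)
        return CellAnnotationTable(sub)


def occupancy(
    table: CellAnnotationTable,
    group: str,
    cluster_space=None,
    by: str | None = None,
) -> ClusterDistribution:
    """Cluster occupancy counts of one sample or one pooled condition.

    Parameters
    ----------
    table
        Joint annotation table.
    group
        A ``sample_id`` or a ``condition`` label.  With ``by=None`` the group
        is looked up among sample ids first, then conditions.
    cluster_space
        Ordered cluster ids to align counts to; defaults to the table's joint
        cluster space.  Must be a superset of the clusters observed in the
        group.
    by
        Force interpretation of ``group`` as ``"sample"`` or ``"condition"``.

    Returns
    -------
    ClusterDistribution
        Counts aligned to ``cluster_space``; unobserved clusters get 0.
    """
    df = table.df
    if by is None:
        if group in table.sample_ids:
            by = "sample"
        elif group in table.conditions:
            by = "condition"
        else:
            raise KeyError(f"group {group!r} is neither a sample_id nor a condition")
    if by not in ("sample", "condition"):
        raise ValueError(f"by must be 'sample' or 'condition', got {by!r}")
    col = "sample_id" if by == "sample" else "condition"
    rows = df[df[col] == group]
    if len(rows) == 0:
        raise KeyError(f"no cells for {col}={group!r}")
    if cluster_space is None:
        cluster_space = table.cluster_space
    cluster_space = tuple(cluster_space)
    observed = rows["cluster"].value_counts()
    extra = set(observed.index) - set(cluster_space)
    if extra:
        raise AlignmentError(
            f"group {group!r} has clusters outside the given cluster space: "
            f"{sorted(extra)}"
        )
    counts = np.array([int(observed.get(c, 0)) for c in cluster_space])
    return ClusterDistribution(cluster_space, counts, label=str(group))


def ks_distance(a: ClusterDistribution, b: ClusterDistribution) -> float:
    """KS distance between two occupancy distributions on the same space.

    ``max_k | CDF_a(k) - CDF_b(k) |`` with CDFs accumulating occupancy
    *proportions* along the shared ascending cluster order.  Symmetric,
    in [0, 1], and 0 iff the proportion vectors are identical.
    """
    if a.cluster_ids != b.cluster_ids:
        raise AlignmentError(
            "distributions are on different cluster spaces; align both with "
            "occupancy(..., cluster_space=...) first"
        )
    cdf_a = np.cumsum(a.proportions)
    cdf_b = np.cumsum(b.proportions)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def pairwise_ks(table: CellAnnotationTable, by: str = "sample") -> pd.DataFrame:
    """Symmetric matrix of KS distances between all samples or conditions.

    Distances are computed on the full joint cluster space, so groups with
    disjoint occupancy still compare meaningfully.  Returns a square frame
    indexed by group labels with zero diagonal.
    """
    if by == "sample":
        groups = table.sample_ids
    elif by == "condition":
        groups = table.conditions
    else:
        raise ValueError(f"by must be 'sample' or 'condition', got {by!r}")
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups to compare, found {len(groups)}")
    space = table.cluster_space
    dists = {g: occupancy(table, g, cluster_space=space, by=by) for g in groups}
    mat = np.zeros((len(groups), len(groups)))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i < j:
                mat[i, j] = mat[j, i] = ks_distance(dists[gi], dists[gj])
    return pd.DataFrame(mat, index=list(groups), columns=list(groups))
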