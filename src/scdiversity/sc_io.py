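"""Readers/writers for 10x-style inputs and a minimal stand-in clusterer.

Supported on-disk formats:

* 10x MTX directory — MatrixMarket triplet ``matrix.mtx`` plus
  ``barcodes.tsv`` and ``features.tsv`` (or the older ``genes.tsv``), each
  optionally gzipped.  Feature files may have 1, 2 or 3 columns
  (id / id+name / id+name+type); only the id column is kept.
* Loupe-dialect cluster CSV — header ``Barcode,Cluster``; the suffix after
  the final ``-`` in each barcode is the library aggregation index.
* Samples sheet CSV — header ``suffix,sample_id,condition`` resolving each
  aggregation suffix to a sample and a condition.

Readers validate loudly: dimension mismatches, duplicate barcodes,
non-integer entries and unmapped suffixes raise :class:`FormatError` naming
the offending file and values, rather than being silently coerced.

``quick_cluster`` is deliberately simple plumbing — library-size scaling,
log1p, truncated SVD, k-means — so end-to-end runs are possible without the
vendor clustering stack whose labels are normally a first-class input.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD

from .cluster_compare import CellAnnotationTable
from .expression_network import ExpressionMatrix

__all__ = [
    "FormatError",
    "quick_cluster",
    "read_10x_mtx",
    "read_annotations",
    "write_10x_mtx",
    "write_annotations",
]


class FormatError(ValueError):
    """Raised for malformed input files, with file context in the message."""


def _find(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path, what: str) -> list[str]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: cannot parse {what} TSV ({exc})") from exc
    if df.shape[1] not in (1, 2, 3):
        raise FormatError(
            f"{path}: expected 1-3 tab-separated columns, found {df.shape[1]}"
        )
    return df.iloc[:, 0].tolist()


def read_10x_mtx(directory) -> ExpressionMatrix:
    """Load a 10x-style MTX directory into an :class:`ExpressionMatrix`.

    Accepts plain or gzipped ``matrix.mtx``, ``barcodes.tsv`` and
    ``features.tsv``/``genes.tsv``.  Validates that identifier counts match
    the matrix header and that all entries are non-negative integers.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    mtx_path = _find(directory, ("matrix.mtx",))
    barcodes_path = _find(directory, ("barcodes.tsv",))
    features_path = _find(directory, ("features.tsv", "genes.tsv"))
    with _open_text(mtx_path) as fh:
        try:
            counts = scipy.io.mmread(fh)
        except Exception as exc:
            raise FormatError(f"{mtx_path}: invalid MatrixMarket file ({exc})") from exc
    counts = sp.csc_matrix(counts)
    barcodes = _read_tsv_column(barcodes_path, "barcode")
    genes = _read_tsv_column(features_path, "feature")
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{mtx_path}: {counts.shape[0]} rows but {features_path.name} "
            f"lists {len(genes)} features"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {counts.shape[1]} columns but {barcodes_path.name} "
            f"lists {len(barcodes)} barcodes"
        )
    if counts.nnz:
        if counts.data.min() < 0:
            raise FormatError(f"{mtx_path}: negative counts present")
        if np.any(counts.data != np.floor(counts.data)):
            raise FormatError(f"{mtx_path}: non-integer counts present")
    return ExpressionMatrix(tuple(genes), tuple(barcodes), counts)


def write_10x_mtx(matrix: ExpressionMatrix, directory) -> Path:
    """Write an :class:`ExpressionMatrix` as a plain (uncompressed) MTX dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        directory / "matrix.mtx", matrix.counts.astype(np.int64), field="integer"
    )
    (directory / "barcodes.tsv").write_text("\n".join(matrix.barcodes) + "\n")
    (directory / "features.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    return directory


def read_annotations(cluster_csv, samples_csv) -> CellAnnotationTable:
    """Join a Loupe-dialect cluster CSV with a samples sheet.

    Each barcode's aggregation suffix (the digits after its final ``-``) is
    looked up in the samples sheet to resolve sample and condition; barcodes
    whose suffix is missing from the sheet are reported together in one
    error.
    """
    cluster_csv, samples_csv = Path(cluster_csv), Path(samples_csv)
    clusters = pd.read_csv(cluster_csv, dtype=str)
    if list(clusters.columns[:2]) != ["Barcode", "Cluster"]:
        raise FormatError(
            f"{cluster_csv}: expected header 'Barcode,Cluster', "
            f"found {list(clusters.columns)}"
        )
    if clusters["Barcode"].duplicated().any():
        dupes = clusters.loc[
            clusters["Barcode"].duplicated(), "Barcode"
        ].head(5).tolist()
        raise FormatError(f"{cluster_csv}: duplicate barcodes, e.g. {dupes}")
    cluster_num = pd.to_numeric(clusters["Cluster"], errors="coerce")
    bad = clusters.loc[
        cluster_num.isna() | (cluster_num != np.floor(cluster_num)), "Cluster"
    ]
    if len(bad):
        raise FormatError(
            f"{cluster_csv}: non-integer cluster labels, e.g. {bad.head(5).tolist()}"
        )

    sheet = pd.read_csv(samples_csv, dtype=str)
    required = ["suffix", "sample_id", "condition"]
    if list(sheet.columns[:3]) != required:
        raise FormatError(
            f"{samples_csv}: expected header 'suffix,sample_id,condition', "
            f"found {list(sheet.columns)}"
        )
    sheet["suffix"] = sheet["suffix"].str.lstrip("-")
    if sheet["suffix"].duplicated().any():
        raise FormatError(f"{samples_csv}: duplicate suffix entries")
    by_suffix = sheet.set_index("suffix")

    suffixes = clusters["Barcode"].str.rsplit("-", n=1).str[-1]
    unmapped = sorted(set(suffixes) - set(by_suffix.index))
    if unmapped:
        raise FormatError(
            f"{cluster_csv}: barcode suffixes not in {samples_csv.name}: "
            f"{['-' + s for s in unmapped]}"
        )
    df = pd.DataFrame(
        {
            "barcode": clusters["Barcode"],
            "sample_id": by_suffix.loc[suffixes, "sample_id"].to_numpy(),
            "condition": by_suffix.loc[suffixes, "condition"].to_numpy(),
            "cluster": cluster_num.astype(np.int64),
        }
    )
    return CellAnnotationTable(df)


def write_annotations(table: CellAnnotationTable, cluster_csv, samples_csv) -> None:
    """Write a table back to the Loupe cluster CSV + samples sheet pair."""
    df = table.df
    pd.DataFrame({"Barcode": df["barcode"], "Cluster": df["cluster"]}).to_csv(
        cluster_csv, index=False
    )
    suffixes = df["barcode"].str.rsplit("-", n=1).str[-1]
    sheet = (
        pd.DataFrame(
            {
                "suffix": suffixes,
                "sample_id": df["sample_id"],
                "condition": df["condition"],
            }
        )
        .drop_duplicates()
        .sort_values("suffix")
    )
    sheet.to_csv(samples_csv, index=False)


def quick_cluster(
    matrix: ExpressionMatrix, k: int, seed: int = 0, n_components: int = 20
) -> np.ndarray:
    """Partition cells into ``k`` clusters; stand-in for platform clustering.

    Pipeline: scale each cell to the median library size, log1p, project to
    at most ``n_components`` principal directions (truncated SVD), k-means.
    Returns integer labels 1..k, one per cell, deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > matrix.n_cells:
        raise ValueError(f"k={k} exceeds the {matrix.n_cells} cells available")
    if k == 1:
        return np.ones(matrix.n_cells, dtype=np.int64)
    x = matrix.counts.T.astype(float).tocsr()  # cells x genes
    totals = np.asarray(x.sum(axis=1)).ravel()
    scale = np.divide(
        np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0,
        totals,
        out=np.ones_like(totals),
        where=totals > 0,
    )
    x = sp.diags(scale) @ x
    x.data = np.log1p(x.data)
    n_comp = min(n_components, matrix.n_genes - 1, matrix.n_cells - 1)
    if n_comp >= 1:
        x = TruncatedSVD(n_components=n_comp, random_state=int(seed)).fit_transform(x)
    else:
        x = x.toarray()
    # generous restarts: with strongly imbalanced cluster sizes k-means++
    # occasionally seeds a large cluster twice and merges two small ones
    labels = KMeans(n_clusters=k, random_state=int(seed), n_init=50).fit_predict(x)
    return labels.astype(np.int64) + 1
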