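"""Synthetic single-cell cohorts with known clonal structure.

Generates genes x cells UMI matrices plus cell annotations for cohorts of
several samples per condition sharing one joint cluster space, so every
pipeline stage — I/O, clustering, occupancy, diversity, comparison,
downsampling — can be exercised against known ground truth.

The generative model is deliberately plain: each cell is assigned a cluster
by a multinomial draw from its sample's true proportion vector, and its UMI
counts are drawn from a negative binomial (gamma-Poisson) whose per-gene
mean is a log-normal baseline shared by all clusters, elevated on a disjoint
block of marker genes specific to the cell's cluster.  This reproduces the
features the diversity pipeline is sensitive to — condition-skewed cluster
occupancy and separable per-cluster expression programs — and none of the
batch effects, doublets or ambient RNA of real droplet data.

The shipped presets encode the qualitative composition patterns of the
cohorts the method targets: a low-diversity "healthy-like" marrow dominated
by a few clusters, a higher-diversity "aml-like" disease state spread over
more clusters (its spectrum dominates the healthy one at every order by
construction), a near-uniform "polyclonal-cd34-like" progenitor pool, and a
"homogeneous-sorted-like" population with one dominant cluster.  The vectors
are synthetic inventions constrained only by that ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cluster_compare import CellAnnotationTable
from .expression_network import ExpressionMatrix

__all__ = [
    "AML_LIKE_P",
    "HEALTHY_LIKE_P",
    "HOMOGENEOUS_SORTED_P",
    "POLYCLONAL_CD34_P",
    "ScenarioSpec",
    "annotation_table_from_proportions",
    "preset_scenarios",
    "simulate_cohort",
    "write_truth",
]

# Synthetic occupancy vectors over a shared 14-cluster space (healthy leaves
# six clusters empty; the disease-like vector is flatter and fully occupied,
# so its diversity spectrum lies strictly above the healthy one at every q).
HEALTHY_LIKE_P: tuple[float, ...] = (
    0.40, 0.24, 0.14, 0.10, 0.06, 0.03, 0.02, 0.01, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
)
AML_LIKE_P: tuple[float, ...] = (
    0.12, 0.11, 0.10, 0.09, 0.085, 0.08, 0.075, 0.07,
    0.065, 0.06, 0.05, 0.04, 0.03, 0.025,
)
POLYCLONAL_CD34_P: tuple[float, ...] = tuple([1.0 / 16] * 16)
HOMOGENEOUS_SORTED_P: tuple[float, ...] = (0.90, 0.04, 0.03, 0.02, 0.01)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    name
        Scenario identifier.
    conditions
        ``(condition_name, n_samples)`` pairs.
    proportions
        True cluster proportion vector per condition; all vectors share one
        cluster space (equal length, clusters numbered 1..S).
    n_cells
        Cells per sample.
    n_genes
        Genes in the expression matrix; must accommodate the disjoint marker
        blocks (``S * markers_per_cluster`` genes).
    markers_per_cluster
        Marker genes elevated in each cluster's program.
    base_mean, base_log_sd
        Location/shape of the log-normal baseline per-gene mean (UMI units).
    marker_mean
        Mean UMI count of a cluster's marker genes.
    dispersion
        Negative-binomial dispersion alpha (variance = mu + alpha * mu^2),
        shared by all genes.
    seed
        Master seed; all randomness derives from it.
    """

    name: str
    conditions: tuple[tuple[str, int], ...]
    proportions: dict[str, tuple[float, ...]]
    n_cells: int = 2000
    n_genes: int = 300
    markers_per_cluster: int = 10
    base_mean: float = 0.2
    base_log_sd: float = 0.5
    marker_mean: float = 8.0
    dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("conditions: at least one condition is required")
        for cond, n in self.conditions:
            if n < 1:
                raise ValueError(f"conditions: {cond!r} needs >= 1 samples")
            if cond not in self.proportions:
                raise ValueError(f"proportions: no vector for condition {cond!r}")
        lengths = {len(v) for v in self.proportions.values()}
        if len(lengths) != 1:
            raise ValueError("proportions: vectors must share one cluster space")
        for cond, p in self.proportions.items():
            arr = np.asarray(p, dtype=float)
            if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise ValueError(
                    f"proportions[{cond!r}]: entries must be >= 0 and sum to 1"
                )
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.n_genes < self.n_clusters * self.markers_per_cluster:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {self.n_clusters} "
                f"clusters x {self.markers_per_cluster} markers"
            )
        for fname in ("base_mean", "base_log_sd", "marker_mean", "dispersion"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")

    @property
    def n_clusters(self) -> int:
        return len(next(iter(self.proportions.values())))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(
            f"{cond}_{i}" for cond, n in self.conditions for i in range(1, n + 1)
        )


def _barcode(index: int, suffix: int, length: int = 16) -> str:
    """Deterministic unique ACGT barcode for a global cell index."""
    bases = "ACGT"
    chars = []
    for _ in range(length):
        chars.append(bases[index % 4])
        index //= 4
    return "".join(reversed(chars)) + f"-{suffix}"


def annotation_table_from_proportions(
    proportions,
    n_cells: int,
    seed: int = 0,
    sample_id: str = "S1",
    condition: str = "cond",
    suffix: int = 1,
) -> CellAnnotationTable:
    """Annotation table alone (no expression) from a true proportion vector.

    Cells are assigned to clusters 1..S by i.i.d. draws from ``proportions``.
    Convenient for composition-only studies such as the downsampling
    protocol, where expression values are irrelevant.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("proportions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    clusters = rng.choice(np.arange(1, p.size + 1), size=n_cells, p=p)
    df = pd.DataFrame(
        {
            "barcode": [_barcode(i, suffix) for i in range(n_cells)],
            "sample_id": sample_id,
            "condition": condition,
            "cluster": clusters,
        }
    )
    return CellAnnotationTable(df)


def _cluster_means(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """(S, n_genes) per-gene NB means: log-normal baseline + marker blocks."""
    baseline = rng.lognormal(
        mean=np.log(spec.base_mean), sigma=spec.base_log_sd, size=spec.n_genes
    )
    means = np.tile(baseline, (spec.n_clusters, 1))
    m = spec.markers_per_cluster
    for c in range(spec.n_clusters):
        means[c, c * m : (c + 1) * m] = spec.marker_mean
    return means


def simulate_cohort(
    spec: ScenarioSpec,
) -> tuple[ExpressionMatrix, CellAnnotationTable, dict]:
    """Simulate a cohort: expression matrix, annotations and ground truth.

    Barcodes carry per-sample aggregation suffixes ("-1", "-2", ... in
    cohort sample order).  The returned truth dict records each sample's
    condition and true cluster proportions.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    means = _cluster_means(spec, rng)
    shape = 1.0 / spec.dispersion  # gamma-Poisson mixture = negative binomial

    barcodes: list[str] = []
    rows = []
    blocks = []
    truth_samples: dict[str, dict] = {}
    cell_index = 0
    for suffix, sample_id in enumerate(spec.sample_ids, start=1):
        condition = sample_id.rsplit("_", 1)[0]
        p = np.asarray(spec.proportions[condition], dtype=float)
        clusters = rng.choice(np.arange(spec.n_clusters), size=spec.n_cells, p=p)
        mu = means[clusters]  # (n_cells, n_genes)
        lam = rng.gamma(shape=shape, scale=mu / shape)
        counts = rng.poisson(lam)
        blocks.append(sp.csc_matrix(counts.T))  # genes x cells
        for c in clusters:
            barcodes.append(_barcode(cell_index, suffix))
            rows.append((barcodes[-1], sample_id, condition, int(c) + 1))
            cell_index += 1
        truth_samples[sample_id] = {
            "condition": condition,
            "proportions": p.tolist(),
        }

    matrix = ExpressionMatrix(
        gene_ids=tuple(f"gene_{g:05d}" for g in range(spec.n_genes)),
        barcodes=tuple(barcodes),
        counts=sp.hstack(blocks, format="csc"),
    )
    table = CellAnnotationTable(
        pd.DataFrame(rows, columns=["barcode", "sample_id", "condition", "cluster"])
    )
    truth = {
        "scenario": spec.name,
        "seed": spec.seed,
        "n_clusters": spec.n_clusters,
        "samples": truth_samples,
        "conditions": {
            cond: list(map(float, spec.proportions[cond]))
            for cond, _ in spec.conditions
        },
    }
    return matrix, table, truth


def preset_scenarios(seed: int = 0, n_cells: int = 2000) -> dict[str, ScenarioSpec]:
    """Named scenario presets covering the qualitative composition patterns.

    ``aml-vs-healthy`` is the two-condition cohort (two samples per
    condition on a shared 14-cluster space); the single-condition presets
    expose each composition pattern on its own.
    """
    return {
        "healthy-like": ScenarioSpec(
            name="healthy-like",
            conditions=(("healthy", 2),),
            proportions={"healthy": HEALTHY_LIKE_P},
            n_cells=n_cells,
            seed=seed,
        ),
        "aml-like": ScenarioSpec(
            name="aml-like",
            conditions=(("aml", 2),),
            proportions={"aml": AML_LIKE_P},
            n_cells=n_cells,
            seed=seed,
        ),
        "aml-vs-healthy": ScenarioSpec(
            name="aml-vs-healthy",
            conditions=(("healthy", 2), ("aml", 2)),
            proportions={"healthy": HEALTHY_LIKE_P, "aml": AML_LIKE_P},
            n_cells=n_cells,
            seed=seed,
        ),
        "polyclonal-cd34-like": ScenarioSpec(
            name="polyclonal-cd34-like",
            conditions=(("cd34", 1),),
            proportions={"cd34": POLYCLONAL_CD34_P},
            n_cells=n_cells,
            n_genes=320,
            seed=seed,
        ),
        "homogeneous-sorted-like": ScenarioSpec(
            name="homogeneous-sorted-like",
            conditions=(("sorted", 1),),
            proportions={"sorted": HOMOGENEOUS_SORTED_P},
            n_cells=n_cells,
            n_genes=100,
            seed=seed,
        ),
    }


def write_truth(truth: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2) + "\n")
    return path
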