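"""Downsampling stability protocol for diversity spectra.

Repeatedly remove a fixed fraction of a sample's cells uniformly at random
(without replacement), recompute occupancy and the diversity qD at a set of
anchor orders, and summarise how much the score moves.  Two modes:

* default — cluster labels from the joint clustering are kept fixed under
  subsampling, isolating the sampling stability of the statistic itself;
* ``recluster_hook`` — a callable re-derives labels on each subsample before
  occupancy, folding clustering-algorithm stability into the measurement.

Each replicate draws its randomness from an independent child of the master
seed (``numpy.random.SeedSequence`` spawn keys), so results are bit-for-bit
reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cluster_compare import CellAnnotationTable
from .core_diversity import ANCHOR_Q, hill_from_proportions

__all__ = [
    "DownsampleResult",
    "RelativeChange",
    "downsample_once",
    "downsample_spectrum",
    "relative_change",
    "write_downsample_tables",
]


@dataclass(frozen=True)
class DownsampleResult:
    """Replicate diversity values from the downsampling protocol."""

    sample_label: str
    q_values: np.ndarray
    replicate_d: np.ndarray  # (n_replicates, len(q_values))
    baseline_d: np.ndarray  # full-data qD per q
    fraction: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        rep = np.asarray(self.replicate_d, dtype=float)
        base = np.asarray(self.baseline_d, dtype=float)
        if rep.shape != (self.n_replicates, q.size) or base.shape != q.shape:
            raise ValueError("inconsistent result dimensions")
        if not np.all(np.isfinite(rep)) or np.any(rep < 1 - 1e-9):
            raise ValueError("replicate diversities must be finite and >= 1")
        object.__setattr__(self, "q_values", q)
        object.__setattr__(self, "replicate_d", rep)
        object.__setattr__(self, "baseline_d", base)


@dataclass(frozen=True)
class RelativeChange:
    """Mean-normalised replicate distributions and per-q summaries."""

    result: DownsampleResult
    normalized_d: np.ndarray  # replicate_d / per-q replicate mean
    summary: pd.DataFrame  # per q: baseline, mean, sd, max |replicate - baseline|


def downsample_once(
    table: CellAnnotationTable, fraction: float, seed
) -> CellAnnotationTable:
    """One uniform without-replacement subsample of ``floor(fraction * n)`` cells.

    ``seed`` may be an int or a ``numpy.random.Generator``/``SeedSequence``.
    Deterministic given the seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(table)
    k = int(np.floor(fraction * n))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {n} cells leaves an empty subsample"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return table.subset(np.sort(idx))


def downsample_spectrum(
    table: CellAnnotationTable,
    fraction: float = 0.5,
    n_replicates: int = 1000,
    q_values: Sequence[float] = ANCHOR_Q,
    seed: int = 0,
    recluster_hook: Callable[[CellAnnotationTable], np.ndarray] | None = None,
    label: str | None = None,
) -> DownsampleResult:
    """Run the downsampling protocol on one annotation table.

    The table is typically the cells of a single sample; occupancy is pooled
    over all of its rows.  ``recluster_hook``, if given, receives each
    subsampled table and returns new integer cluster labels (one per row)
    that replace the stored ones before occupancy is computed.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 cells to downsample")
    q_values = np.asarray(q_values, dtype=float)
    if q_values.size == 0 or np.any(q_values < 0) or not np.all(np.isfinite(q_values)):
        raise ValueError("q_values must be finite and >= 0")

    def _occupancy_proportions(t: CellAnnotationTable) -> np.ndarray:
        counts = t.df["cluster"].value_counts()
        return (counts / counts.sum()).to_numpy()

    baseline_p = _occupancy_proportions(table)
    baseline_d = np.array([hill_from_proportions(baseline_p, q) for q in q_values])

    replicate_d = np.empty((n_replicates, q_values.size))
    for r in range(n_replicates):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(r,))
        sub = downsample_once(table, fraction, np.random.default_rng(child))
        if recluster_hook is not None:
            labels = np.asarray(recluster_hook(sub))
            sub = CellAnnotationTable(sub.df.assign(cluster=labels))
        p = _occupancy_proportions(sub)
        replicate_d[r] = [hill_from_proportions(p, q) for q in q_values]
    return DownsampleResult(
        sample_label=label or "+".join(map(str, table.sample_ids)),
        q_values=q_values,
        replicate_d=replicate_d,
        baseline_d=baseline_d,
        fraction=float(fraction),
        n_replicates=int(n_replicates),
        seed=int(seed),
    )


def relative_change(result: DownsampleResult) -> RelativeChange:
    """Normalise each per-q replicate distribution by its mean and summarise.

    ``normalized_d[r, j] = replicate_d[r, j] / mean_r replicate_d[., j]``, so
    every normalised column has mean exactly 1.  The summary also reports the
    maximum absolute deviation from the full-data baseline in diversity
    (effective-cluster) units.
    """
    if result.n_replicates < 1:
        raise ValueError("result has no replicates")
    means = result.replicate_d.mean(axis=0)
    normalized = result.replicate_d / means
    abs_dev = np.abs(result.replicate_d - result.baseline_d)
    summary = pd.DataFrame(
        {
            "label": result.sample_label,
            "q": result.q_values,
            "baseline_d": result.baseline_d,
            "mean_d": means,
            "sd_d": result.replicate_d.std(axis=0, ddof=1)
            if result.n_replicates > 1
            else np.zeros_like(means),
            "max_abs_change": abs_dev.max(axis=0),
        }
    )
    return RelativeChange(result=result, normalized_d=normalized, summary=summary)


def write_downsample_tables(change: RelativeChange, outdir) -> tuple[Path, Path]:
    """Write the long replicate table and the per-q summary as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = change.result
    n_rep, n_q = res.replicate_d.shape
    long = pd.DataFrame(
        {
            "label": res.sample_label,
            "q": np.tile(res.q_values, n_rep),
            "replicate": np.repeat(np.arange(n_rep), n_q),
            "d": res.replicate_d.ravel(),
            "normalized_d": change.normalized_d.ravel(),
        }
    )
    long_path = outdir / "downsample_replicates.csv"
    summary_path = outdir / "downsample_summary.csv"
    long.to_csv(long_path, index=False)
    change.summary.to_csv(summary_path, index=False)
    return long_path, summary_path
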