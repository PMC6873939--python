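"""Generalized (Hill-number) diversity of cluster occupancy distributions.

The central quantity is the diversity of order ``q``,

    qD = ( sum_i p_i^q )^(1/(1-q)),       q >= 0, q != 1,
    1D = exp( -sum_i p_i ln p_i )          (the q -> 1 limit),

where ``p_i`` is the fraction of cells assigned to cluster ``i``.  qD is an
*effective number of clusters*: a sample spread evenly over S clusters has
qD = S at every order.  Low q weighs rare clusters (q = 0 is richness, the
count of occupied clusters); q = 1 is the exponential of Shannon entropy;
q = 2 is the inverse Simpson index; q -> infinity tends to the Berger-Parker
dominance 1/max(p).  Scanning q therefore turns a single composition vector
into a diversity *spectrum* that separates rare-clone structure from
dominant-clone structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ANCHOR_Q",
    "ClusterDistribution",
    "DiversitySpectrum",
    "InvalidDistributionError",
    "NamedIndices",
    "default_q_grid",
    "diversity_spectrum",
    "hill_diversity",
    "hill_from_proportions",
    "named_indices",
    "write_spectra",
]

#: Anchor orders of diversity reported by the downsampling protocol and used
#: throughout: richness-like (0.01, 0.1), Shannon (1), inverse Simpson (2),
#: and dominance-weighted (10, 100).
ANCHOR_Q: tuple[float, ...] = (0.01, 0.1, 1.0, 2.0, 10.0, 100.0)

#: Below this |q - 1| the exact Shannon-limit branch is used instead of the
#: generic power-sum formula, which suffers catastrophic cancellation there.
_Q1_TOLERANCE = 1e-9


class InvalidDistributionError(ValueError):
    """Raised when cluster counts cannot form a probability distribution."""


@dataclass(frozen=True)
class ClusterDistribution:
    """Cluster occupancy counts for one sample, condition, or pool.

    Parameters
    ----------
    cluster_ids
        Cluster identifiers in strictly ascending canonical order.
    counts
        Non-negative integer cell count per cluster, aligned with
        ``cluster_ids``.  At least one count must be positive.
    label
        Optional sample/condition identifier carried for provenance.
    """

    cluster_ids: tuple
    counts: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        ids = tuple(self.cluster_ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(ids) != counts.shape[0]:
            raise InvalidDistributionError(
                f"cluster_ids ({len(ids)}) and counts ({counts.shape}) "
                "must be 1-D and the same length"
            )
        if len(ids) == 0:
            raise InvalidDistributionError("distribution has no clusters")
        if len(set(ids)) != len(ids):
            raise InvalidDistributionError("cluster_ids are not unique")
        if any(a >= b for a, b in zip(ids, ids[1:])):
            raise InvalidDistributionError(
                "cluster_ids must be in strictly ascending order"
            )
        if not np.issubdtype(counts.dtype, np.number):
            raise InvalidDistributionError("counts must be numeric")
        if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
            raise InvalidDistributionError("counts must be non-negative integers")
        if counts.sum() <= 0:
            raise InvalidDistributionError("all cluster counts are zero")
        object.__setattr__(self, "cluster_ids", ids)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_cells(self) -> int:
        """Total number of cells across clusters."""
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Occupancy fractions ``p_i`` (sum to 1)."""
        return self.counts / self.counts.sum()

    @property
    def richness(self) -> int:
        """Number of occupied clusters (counts > 0)."""
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class DiversitySpectrum:
    """qD evaluated on a grid of orders q for one source distribution."""

    q_grid: np.ndarray
    d_values: np.ndarray
    source_label: str | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        d = np.asarray(self.d_values, dtype=float)
        if q.ndim != 1 or q.shape != d.shape:
            raise ValueError("q_grid and d_values must be equal-length 1-D arrays")
        if q.size == 0:
            raise ValueError("q_grid is empty")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "d_values", d)

    def __len__(self) -> int:
        return self.q_grid.size


@dataclass(frozen=True)
class NamedIndices:
    """The classical diversity indices that arise as special orders of qD."""

    richness: int
    shannon_log: float
    simpson_inverse: float
    berger_parker: float


def _validate_q(q: float) -> float:
    q = float(q)
    if not np.isfinite(q) or q < 0:
        raise ValueError(f"order of diversity q must be finite and >= 0, got {q}")
    return q


def hill_from_proportions(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Diversity of order ``q`` of a proportion vector.

    Zero entries are dropped (they contribute nothing at any order, including
    q = 0, where the result is the count of positive entries).  Computation is
    carried out in log space so that orders as large as q = 100 do not
    underflow for small proportions.
    """
    q = _validate_q(q)
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise InvalidDistributionError("proportion vector has no mass")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise InvalidDistributionError(f"proportions sum to {total}, expected 1")
    if q == 0.0:
        return float(p.size)
    logp = np.log(p)
    if abs(q - 1.0) < _Q1_TOLERANCE:
        # exact Shannon limit; the generic branch divides by 1 - q
        return float(np.exp(-np.sum(p * logp)))
    return float(np.exp(logsumexp(q * logp) / (1.0 - q)))


def hill_diversity(dist: ClusterDistribution, q: float) -> float:
    """Effective number of clusters of order ``q`` for ``dist``.

    Examples
    --------
    >>> import numpy as np
    >>> d = ClusterDistribution((1, 2, 3), np.array([2, 1, 1]))
    >>> round(hill_diversity(d, 2), 6)   # inverse Simpson of (1/2, 1/4, 1/4)
    2.666667
    """
    return hill_from_proportions(dist.proportions, q)


def default_q_grid(
    q_min: float = 0.01, q_max: float = 100.0, n_points: int = 100
) -> np.ndarray:
    """Log-spaced grid on [q_min, q_max] augmented with the anchor orders.

    Anchors inside the range are always included exactly so that spectra can
    be read off at the classical indices without interpolation.
    """
    if q_min <= 0 or q_max <= q_min:
        raise ValueError("require 0 < q_min < q_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.geomspace(q_min, q_max, n_points)
    anchors = [a for a in ANCHOR_Q if q_min <= a <= q_max]
    return np.unique(np.concatenate([grid, anchors]))


def diversity_spectrum(
    dist: ClusterDistribution,
    q_grid: Sequence[float] | np.ndarray | None = None,
    label: str | None = None,
) -> DiversitySpectrum:
    """Evaluate the diversity spectrum of ``dist`` over ``q_grid``.

    With ``q_grid=None`` the default grid of :func:`default_q_grid` is used.
    The resulting ``d_values`` are non-increasing in q (a standard property
    of Hill numbers).
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size == 0:
        raise ValueError("q_grid is empty")
    if np.any(q_grid < 0) or not np.all(np.isfinite(q_grid)):
        raise ValueError("all orders q must be finite and >= 0")
    if q_grid.ndim != 1 or np.any(np.diff(q_grid) <= 0):
        raise ValueError("q_grid must be 1-D and strictly increasing")
    p = dist.proportions
    d = np.array([hill_from_proportions(p, q) for q in q_grid])
    return DiversitySpectrum(q_grid, d, label if label is not None else dist.label)


def named_indices(dist: ClusterDistribution) -> NamedIndices:
    """Richness, Shannon (log scale), inverse Simpson and Berger-Parker.

    These are the special cases of qD at q = 0, 1, 2 and infinity:
    ``exp(shannon_log) == hill_diversity(dist, 1)`` and
    ``berger_parker`` is the q -> infinity limit.
    """
    p = dist.proportions
    p = p[p > 0]
    shannon = float(-np.sum(p * np.log(p)))
    return NamedIndices(
        richness=int(p.size),
        shannon_log=shannon,
        simpson_inverse=float(1.0 / np.sum(p**2)),
        berger_parker=float(1.0 / p.max()),
    )


def write_spectra(spectra: Sequence[DiversitySpectrum], path) -> None:
    """Write spectra as long-format CSV with header ``label,q,d``."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {"label": s.source_label or "", "q": s.q_grid, "d": s.d_values}
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
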