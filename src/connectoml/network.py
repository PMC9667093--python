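"""From node time series to binary graphs over a sparsity-threshold grid.

Edges are Pearson correlations between node time series, variance-stabilised
by Fisher's r-to-z transform, then binarized at each sparsity level S by
keeping the top-ranked connections so the resulting density is exactly S.
Because ranking is invariant to any strictly increasing transform, graphs
built from r and from z are identical; the z matrix is what gets stored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdGrid",
    "ConnectivityMatrix",
    "BinaryGraphStack",
    "default_grid",
    "pearson_matrix",
    "fisher_z",
    "edge_count",
    "binarize_stack",
]

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ThresholdGrid:
    """Ordered sparsity levels S (fraction of retained edges)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if not v:
            raise ValueError("empty threshold grid")
        if any(not 0 < s <= 1 for s in v):
            raise ValueError("sparsity values must lie in (0, 1]")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sparsity values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def label(self, s: float) -> str:
        return f"{s:.2f}"


def default_grid() -> ThresholdGrid:
    """S = 0.05, 0.10, ..., 0.50 — ten thresholds."""
    return ThresholdGrid(tuple(round(0.05 * k, 2) for k in range(1, 11)))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Fisher-z connectivity: symmetric, zero diagonal, finite."""

    z: np.ndarray
    subject: str = ""

    def __post_init__(self) -> None:
        z = self.z
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectivity must be square")
        if not np.allclose(z, z.T):
            raise ValueError("connectivity must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("connectivity entries must be finite")
        if not np.allclose(np.diag(z), 0):
            raise ValueError("connectivity diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class BinaryGraphStack:
    """Binary adjacency per threshold; edge sets are nested across S."""

    grid: ThresholdGrid
    adjacency: np.ndarray  # n_thresholds x n x n, dtype uint8
    subject: str = ""

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]

    def graph_at(self, s: float) -> np.ndarray:
        return self.adjacency[self.grid.values.index(s)]

    def edge_counts(self) -> np.ndarray:
        return np.array([a.sum() // 2 for a in self.adjacency])


def pearson_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation of node time series (timepoints x nodes)."""
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2:
        raise ValueError("timeseries must be 2-D (timepoints x nodes)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series at node(s) {dead.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray, subject: str = "") -> ConnectivityMatrix:
    """Fisher r-to-z (atanh) with the diagonal zeroed.

    Correlations with |r| >= 1 - 1e-7 (e.g. duplicated nodes) are clipped
    before the transform so z stays finite; a warning is emitted.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= _CLIP):
        warnings.warn("off-diagonal |r| ~ 1 clipped before Fisher transform")
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z=z, subject=subject)


def edge_count(s: float, n_nodes: int) -> int:
    """Edges needed for sparsity S: round-half-away-from-zero of S*n(n-1)/2."""
    if not 0 < s <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    max_edges = n_nodes * (n_nodes - 1) // 2
    k = max(1, math.floor(s * max_edges + 0.5))
    if k > max_edges:
        raise ValueError(f"edge count {k} exceeds maximum {max_edges}")
    return k


def binarize_stack(
    conn: ConnectivityMatrix | np.ndarray,
    grid: ThresholdGrid | None = None,
    rank: str = "signed",
) -> BinaryGraphStack:
    """Threshold a connectivity matrix at every sparsity level.

    At each S the ``edge_count(S, n)`` strongest connections become edges.
    ``rank='signed'`` orders by z descending (strongest positive first, the
    binary-network convention); ``rank='absolute'`` orders by |z|.  Ties at
    the cutoff break lexicographically on the upper-triangle (i, j) pair, so
    binarization is total and deterministic and the edge sets are nested
    across thresholds.
    """
    if grid is None:
        grid = default_grid()
    if isinstance(conn, np.ndarray):
        conn = ConnectivityMatrix(z=np.asarray(conn, dtype=float))
    if rank not in ("signed", "absolute"):
        raise ValueError("rank must be 'signed' or 'absolute'")
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = conn.z[iu, ju]
    key = np.abs(w) if rank == "absolute" else w
    order = np.lexsort((ju, iu, -key))  # key desc, then (i, j) asc
    stack = np.zeros((len(grid), n, n), dtype=np.uint8)
    for t, s in enumerate(grid.values):
        k = edge_count(s, n)
        sel = order[:k]
        adj = stack[t]
        adj[iu[sel], ju[sel]] = 1
        adj[ju[sel], iu[sel]] = 1
    return BinaryGraphStack(grid=grid, adjacency=stack, subject=conn.subject)


def connectivity_from_timeseries(
    timeseries: np.ndarray, subject: str = ""
) -> ConnectivityMatrix:
    """Convenience: Pearson then Fisher z in one call."""
    return fisher_z(pearson_matrix(timeseries), subject=subject)
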