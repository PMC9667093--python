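"""Topological metrics of binary graphs.

Seven global metrics — clustering coefficient (Cp), characteristic path
length (Lp), their random-network-normalized forms gamma and lambda, the
small-worldness sigma = gamma/lambda, global efficiency (Eglobal) and
network local efficiency (Elocal) — and five nodal metrics: nodal
clustering (NCp), nodal efficiency (Ne), nodal local efficiency (NLe),
degree centrality (DC) and normalized betweenness centrality (BC).

Conventions (thresholded graphs are routinely disconnected at low density):
Lp averages over reachable pairs only; efficiency treats 1/inf as 0;
clustering of a degree-<2 node is 0 and Cp is the plain mean over all nodes
(not the transitivity ratio).  Normalization uses a degree-preserving
double-edge-swap (Maslov–Sneppen) null ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eglobal", "Elocal")
NODAL_METRICS = ("NCp", "Ne", "NLe", "DC", "BC")


def _as_adj(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a.astype(np.uint8)


def degree_centrality(adj: np.ndarray) -> np.ndarray:
    """DC: number of edges incident to each node (row sums)."""
    return _as_adj(adj).sum(axis=1).astype(int)


def nodal_clustering(adj: np.ndarray) -> np.ndarray:
    """NCp_i = 2 t_i / (k_i (k_i - 1)); 0 for degree < 2."""
    a = _as_adj(adj).astype(float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def clustering_coefficient(adj: np.ndarray) -> float:
    """Cp: unweighted mean of NCp over all nodes."""
    return float(nodal_clustering(adj).mean())


def shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """Unweighted BFS distances; unreachable pairs are +inf.

    Implemented by saturating boolean matrix products (level-synchronous
    BFS from all sources at once), which beats sparse-graph routines at the
    few-hundred-node scale these networks live at.
    """
    a = _as_adj(adj).astype(bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = np.eye(n, dtype=bool)
    frontier = reach.copy()
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier @ a) & ~reach
        if not nxt.any():
            break
        dist[nxt] = d
        reach |= nxt
        frontier = nxt
    return dist


def characteristic_path_length(dist: np.ndarray) -> float:
    """Lp: mean distance over reachable off-diagonal pairs."""
    off = ~np.eye(dist.shape[0], dtype=bool)
    finite = dist[off][np.isfinite(dist[off])]
    if finite.size == 0:
        raise ValueError("Lp undefined: the graph has no edges")
    return float(finite.mean())


def global_efficiency(dist: np.ndarray) -> float:
    """Eglobal: mean of 1/d over off-diagonal pairs (1/inf = 0)."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist[off]), 1.0 / dist[off], 0.0)
    return float(inv.mean())


def nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    """Ne_i: mean of 1/d(i, j) over j != i."""
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    """NLe_i: global efficiency of the subgraph induced by i's neighbors."""
    a = _as_adj(adj)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(shortest_path_lengths(sub))
    return out


def local_efficiency(adj: np.ndarray) -> float:
    """Elocal: unweighted mean of NLe over all nodes."""
    return float(nodal_local_efficiency(adj).mean())


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """BC: Brandes betweenness, normalized by (n-1)(n-2)/2 to [0, 1]."""
    a = _as_adj(adj)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(a.shape[0])])


def rewire_preserving_degrees(
    adj: np.ndarray,
    swaps_per_edge: float = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``swaps_per_edge * |E|`` accepted swaps; each swap picks two
    edges (a, b), (c, d) and rewires to (a, d), (c, b) when that keeps the
    graph simple.  If acceptance stalls (rigid graphs such as complete
    graphs), returns the best effort after a bounded number of attempts with
    a warning.  The degree sequence is exactly preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = _as_adj(adj).copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = len(iu)
    if m < 2:
        return a
    edges = [(int(u), int(v)) for u, v in zip(iu, ju)]
    eset = set(edges)
    target = int(round(swaps_per_edge * m))
    max_attempts = max(100, 20 * target)
    accepted = attempts = 0
    batch = max(256, target)
    pair_list: list = []
    flip_list: list = []
    buf_pos = batch  # force an initial draw
    while accepted < target and attempts < max_attempts:
        if buf_pos >= batch:  # refill RNG buffers in bulk; cheap per attempt
            pair_list = rng.integers(0, m, size=(batch, 2)).tolist()
            flip_list = (rng.random(batch) < 0.5).tolist()
            buf_pos = 0
        e1, e2 = pair_list[buf_pos]
        flip = flip_list[buf_pos]
        buf_pos += 1
        attempts += 1
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip:
            x, y = y, x
        # proposed: (u, y) and (x, v)
        if u == x or u == y or v == x or v == y:
            continue
        new1 = (u, y) if u < y else (y, u)
        new2 = (x, v) if x < v else (v, x)
        if new1 in eset or new2 in eset:
            continue
        eset.discard(edges[e1])
        eset.discard(edges[e2])
        eset.add(new1)
        eset.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        accepted += 1
    a[:] = 0
    for u, v in eset:
        a[u, v] = a[v, u] = 1
    if accepted < target:
        warnings.warn(
            f"degree-preserving rewiring stalled: {accepted}/{target} swaps accepted"
        )
    return a


@dataclass(frozen=True)
class NullEnsemble:
    """Degree-matched random-graph reference for gamma/lambda/sigma."""

    n_random: int = 100
    swaps_per_edge: float = 10
    seed: int = 0

    def reference_means(self, adj: np.ndarray) -> tuple[float, float]:
        """Mean Cp and mean Lp over the rewired ensemble."""
        rng = np.random.default_rng(self.seed)
        cps, lps = [], []
        for _ in range(self.n_random):
            r = rewire_preserving_degrees(adj, self.swaps_per_edge, rng)
            cps.append(clustering_coefficient(r))
            lps.append(characteristic_path_length(shortest_path_lengths(r)))
        return float(np.mean(cps)), float(np.mean(lps))


def small_world_indices(
    adj: np.ndarray, ensemble: NullEnsemble
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against the degree-preserving null ensemble."""
    cp = clustering_coefficient(adj)
    lp = characteristic_path_length(shortest_path_lengths(adj))
    cp_rand, lp_rand = ensemble.reference_means(adj)
    if cp_rand == 0 or lp_rand == 0:
        raise ValueError("null ensemble mean Cp or Lp is zero; gamma/lambda undefined")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return gamma, lam, gamma / lam


def compute_subject_metrics(
    stack, n_random: int = 100, swaps_per_edge: float = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """All metrics for one subject's binary graph stack.

    Returns ``(global_vals, nodal_vals)`` with shapes
    (7, n_thresholds) ordered as :data:`GLOBAL_METRICS` and
    (5, n_thresholds, n_nodes) ordered as :data:`NODAL_METRICS`.
    The null ensemble for threshold t is seeded ``seed + t`` so results are
    reproducible per (subject, threshold).
    """
    n_thr = len(stack.grid)
    n = stack.n_nodes
    gvals = np.empty((len(GLOBAL_METRICS), n_thr))
    nvals = np.empty((len(NODAL_METRICS), n_thr, n))
    for t in range(n_thr):
        adj = stack.adjacency[t]
        dist = shortest_path_lengths(adj)
        ncp = nodal_clustering(adj)
        nle = nodal_local_efficiency(adj)
        cp = float(ncp.mean())
        lp = characteristic_path_length(dist)
        ens = NullEnsemble(n_random=n_random, swaps_per_edge=swaps_per_edge,
                           seed=seed + t)
        cp_rand, lp_rand = ens.reference_means(adj)
        if cp_rand == 0 or lp_rand == 0:
            raise ValueError("null ensemble mean Cp or Lp is zero")
        gamma = cp / cp_rand
        lam = lp / lp_rand
        gvals[:, t] = (cp, lp, gamma, lam, gamma / lam,
                       global_efficiency(dist), float(nle.mean()))
        nvals[0, t] = ncp
        nvals[1, t] = nodal_efficiency(dist)
        nvals[2, t] = nle
        nvals[3, t] = degree_centrality(adj)
        nvals[4, t] = betweenness_centrality(adj)
    return gvals, nvals
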