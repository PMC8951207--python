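"""Sparsity thresholding and binary graph-theory metrics.

A weighted PLI matrix is binarized by *proportional* thresholding: at sparsity
S the strongest ``round(S * N(N-1)/2)`` off-diagonal weights become edges, so
every subject's graph has the same edge count and group differences reflect
topology rather than mean connectivity.  An absolute-threshold mode is also
available.  On the binary graph four global metrics are computed:

* characteristic path length ``L_p`` -- mean shortest-path hop count over
  connected ordered node pairs (graphs with unreachable pairs are flagged
  fragmented and averaged over connected pairs only);
* clustering coefficient ``C_c`` -- mean over nodes of ``2 t_i / (k_i (k_i - 1))``
  with ``t_i`` the triangle count at node i (0 for degree < 2);
* global efficiency ``E_global`` -- mean over ordered pairs of ``1 / d_ij``
  with ``1/inf = 0``;
* local efficiency ``E_local`` -- mean over nodes of the global efficiency of
  the subgraph induced on each node's neighbours (0 for degree < 2).

All metrics are hand-rolled on numpy (BFS hop counts) and are checked against
an independent graph library in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .connectivity import PLIMatrix
from .preprocess import Band

__all__ = [
    "default_sparsity_grid", "BinaryGraph", "TopologyCurve", "METRICS",
    "binarize_by_sparsity", "binarize_by_threshold", "shortest_path_lengths",
    "characteristic_path_length", "clustering_coefficient",
    "global_efficiency", "local_efficiency", "topology_curves",
]

METRICS = ("lp", "cc", "eglobal", "elocal")


def default_sparsity_grid() -> np.ndarray:
    """The 36-point sparsity grid 0.05, 0.06, ..., 0.40."""
    return np.arange(5, 41) / 100.0


@dataclass(frozen=True)
class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal, plus its sparsity level."""

    adjacency: np.ndarray
    sparsity: float | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _weights_as_array(matrix) -> np.ndarray:
    if isinstance(matrix, PLIMatrix):
        return matrix.values
    w = np.asarray(matrix, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    return w


def binarize_by_sparsity(matrix, sparsity: float) -> BinaryGraph:
    """Keep the top ``round(S * N(N-1)/2)`` strongest edges.

    Ties at the cutoff are broken deterministically by lexicographic node-pair
    order (lower (i, j) wins).
    """
    if not (0.0 < sparsity < 1.0):
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    w = _weights_as_array(matrix)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m = _round_half_up(sparsity * n * (n - 1) / 2.0)
    # stable sort on (-weight, i, j): lexsort keys are last-key-major
    order = np.lexsort((ju, iu, -w[iu, ju]))[:m]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[order], ju[order]] = 1
    adj |= adj.T
    return BinaryGraph(adj, sparsity=sparsity)


def binarize_by_threshold(matrix, threshold: float) -> BinaryGraph:
    """Absolute-threshold mode: edges where weight > threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    w = _weights_as_array(matrix)
    adj = (w > threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    adj = adj | adj.T
    return BinaryGraph(adj, sparsity=None)


def _adjacency(graph) -> np.ndarray:
    return graph.adjacency if isinstance(graph, BinaryGraph) else BinaryGraph(graph).adjacency


def shortest_path_lengths(graph) -> np.ndarray:
    """All-pairs BFS hop distances; unreachable pairs are infinite."""
    a = _adjacency(graph).astype(np.int64)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while frontier.any():
        d += 1
        nxt = ((frontier.astype(np.int64) @ a) > 0) & ~reached
        dist[nxt] = d
        reached |= nxt
        frontier = nxt
    return dist


def _is_fragmented(dist: np.ndarray) -> bool:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    return bool(np.isinf(dist[off]).any())


def characteristic_path_length(graph, dist: np.ndarray | None = None) -> float:
    """Mean hop distance over *connected* ordered pairs (spec Eq. for L_p).

    Raises on an edgeless graph.  Use :func:`shortest_path_lengths` plus
    ``numpy.isinf`` (or :func:`topology_curves`) to detect fragmentation.
    """
    a = _adjacency(graph)
    if a.sum() == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    if dist is None:
        dist = shortest_path_lengths(a)
    off = ~np.eye(dist.shape[0], dtype=bool)
    vals = dist[off]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean())


def clustering_coefficient(graph) -> float:
    a = _adjacency(graph).astype(np.int64)
    k = a.sum(axis=1)
    t = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return float(ci.mean())


def global_efficiency(graph, dist: np.ndarray | None = None) -> float:
    a = _adjacency(graph)
    n = a.shape[0]
    if n < 2:
        return 0.0
    if dist is None:
        dist = shortest_path_lengths(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[np.isinf(dist[off])] = 0.0
    return float(inv.mean())


def local_efficiency(graph) -> float:
    a = _adjacency(graph)
    n = a.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        eff[i] = global_efficiency(BinaryGraph(sub))
    return float(eff.mean())


@dataclass(frozen=True)
class TopologyCurve:
    """The four graph metrics evaluated over a sparsity grid for one subject/band."""

    sparsity: np.ndarray
    lp: np.ndarray
    cc: np.ndarray
    eglobal: np.ndarray
    elocal: np.ndarray
    fragmented: np.ndarray
    band: str | None = None
    subject: str | None = None

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS:
            raise KeyError(f"unknown metric {name!r}; choose from {METRICS}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (subject, band, sparsity, metric, value, fragmented)."""
        rows = []
        for m in METRICS:
            vals = self.metric(m)
            for s, v, fr in zip(self.sparsity, vals, self.fragmented):
                rows.append((self.subject, self.band, float(s), m, float(v), bool(fr)))
        return pd.DataFrame(rows, columns=["subject", "band", "sparsity", "metric", "value", "fragmented"])


def topology_curves(
    matrix,
    grid: Iterable[float] | None = None,
    *,
    band: str | None = None,
    subject: str | None = None,
) -> TopologyCurve:
    """Evaluate all four metrics at every sparsity of the grid."""
    grid = default_sparsity_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be a non-empty strictly increasing 1-D sequence")
    w = _weights_as_array(matrix)
    band = band or (matrix.band.name if isinstance(matrix, PLIMatrix) and matrix.band else None)
    lp = np.empty(grid.size)
    cc = np.empty(grid.size)
    eg = np.empty(grid.size)
    el = np.empty(grid.size)
    frag = np.zeros(grid.size, dtype=bool)
    for idx, s in enumerate(grid):
        g = binarize_by_sparsity(w, float(s))
        dist = shortest_path_lengths(g)
        frag[idx] = _is_fragmented(dist)
        lp[idx] = characteristic_path_length(g, dist)
        cc[idx] = clustering_coefficient(g)
        eg[idx] = global_efficiency(g, dist)
        el[idx] = local_efficiency(g)
    return TopologyCurve(grid, lp, cc, eg, el, frag, band=band, subject=subject)
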