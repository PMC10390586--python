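"""Cluster (connected-component) statistics of activity and spin rasters.

A cluster is a maximal set of nodes sharing the same type of activity,
connected through the network's structural adjacency (undirected support
``w_ij + w_ji > 0``).  Two modes:

* ``active_only`` — only nodes with value 1 form clusters (excitable
  dynamics); an isolated active node is a cluster of size 1.
* ``same_value`` — every node belongs to the cluster of its own value
  (Ising domains of +1 and -1 spins).

The two largest momentary sizes ``S1(t) >= S2(t)`` are the percolation-style
order parameters tracked across control-parameter sweeps; their ordering
decomposition over fully disconnected subsystems explains how a divided
system can lose the interior S2 peak while each part stays critical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .networks import WeightedNetwork, Parcellation

__all__ = [
    "ClusterSeries",
    "find_clusters",
    "largest_two",
    "cluster_series",
    "subsystem_series",
    "time_average",
    "ordering_decomposition",
]


@dataclass(frozen=True)
class ClusterSeries:
    """Per-time-step sizes of the largest (``s1``) and second-largest
    (``s2``) cluster, for the whole system or one labelled subsystem."""

    s1: np.ndarray
    s2: np.ndarray
    scope: str = "whole"

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1)
        s2 = np.asarray(self.s2)
        if s1.shape != s2.shape or s1.ndim != 1:
            raise ValueError("s1 and s2 must be 1-D and aligned")
        if np.any(s2 > s1) or np.any(s2 < 0):
            raise ValueError("require s1(t) >= s2(t) >= 0")
        object.__setattr__(self, "s1", s1)
        object.__setattr__(self, "s2", s2)

    @property
    def t_sim(self) -> int:
        return self.s1.size


def find_clusters(
    state: np.ndarray, net: WeightedNetwork, mode: str = "active_only"
) -> np.ndarray:
    """All cluster sizes for one momentary state, sorted descending.

    Uses scipy's connected-components labelling on the masked support; the
    compiled per-time-step kernel in :func:`cluster_series` is cross-checked
    against this routine.
    """
    state = np.asarray(state)
    if state.shape != (net.n_nodes,):
        raise ValueError("state length must match the network")
    if mode not in ("active_only", "same_value"):
        raise ValueError(f"unknown mode: {mode!r}")

    row, col = np.nonzero(net.support())
    if mode == "active_only":
        eligible = state == 1
    else:
        eligible = np.ones(state.size, dtype=bool)
    keep = (state[row] == state[col]) & eligible[row] & eligible[col]
    adj = csr_matrix(
        (np.ones(int(keep.sum())), (row[keep], col[keep])), shape=(state.size, state.size)
    )
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels[eligible]) if eligible.any() else np.array([], dtype=int)
    sizes = sizes[sizes > 0]
    return np.sort(sizes)[::-1]


def largest_two(sizes) -> tuple[int, int]:
    """First two entries of a descending size list, padding with zeros
    (a single-cluster or empty configuration has S2 = 0)."""
    sizes = list(sizes)
    s1 = sizes[0] if len(sizes) >= 1 else 0
    s2 = sizes[1] if len(sizes) >= 2 else 0
    return s1, s2


@njit(cache=True)
def _series_kernel(states, row, col, eligible, active_only):  # pragma: no cover
    """For each time step: union-find over same-value edges restricted to
    eligible nodes, then the two largest component sizes."""
    n, t_sim = states.shape
    n_edges = row.shape[0]
    s1 = np.zeros(t_sim, dtype=np.int64)
    s2 = np.zeros(t_sim, dtype=np.int64)
    parent = np.empty(n, dtype=np.int64)
    count = np.empty(n, dtype=np.int64)
    for t in range(t_sim):
        for i in range(n):
            parent[i] = i
        for e in range(n_edges):
            a = row[e]
            b = col[e]
            if not (eligible[a] and eligible[b]):
                continue
            va = states[a, t]
            if va != states[b, t]:
                continue
            if active_only and va != 1:
                continue
            ra = a
            while parent[ra] != ra:
                parent[ra] = parent[parent[ra]]
                ra = parent[ra]
            rb = b
            while parent[rb] != rb:
                parent[rb] = parent[parent[rb]]
                rb = parent[rb]
            if ra != rb:
                parent[rb] = ra
        count[:] = 0
        for i in range(n):
            if not eligible[i]:
                continue
            if active_only and states[i, t] != 1:
                continue
            r = i
            while parent[r] != r:
                parent[r] = parent[parent[r]]
                r = parent[r]
            count[r] += 1
        best1 = 0
        best2 = 0
        for i in range(n):
            c = count[i]
            if c > best1:
                best2 = best1
                best1 = c
            elif c > best2:
                best2 = c
        s1[t] = best1
        s2[t] = best2
    return s1, s2


def cluster_series(
    raster: np.ndarray,
    net: WeightedNetwork,
    mode: str = "active_only",
    node_mask: np.ndarray | None = None,
    scope: str = "whole",
) -> ClusterSeries:
    """Largest and second-largest cluster sizes at every time step of a
    ``(n, t_sim)`` raster, optionally restricted to the subgraph induced by
    ``node_mask``."""
    raster = np.ascontiguousarray(raster)
    if raster.ndim != 2 or raster.shape[0] != net.n_nodes:
        raise ValueError("raster must be (n_nodes, t_sim)")
    if mode not in ("active_only", "same_value"):
        raise ValueError(f"unknown mode: {mode!r}")
    if node_mask is None:
        node_mask = np.ones(net.n_nodes, dtype=bool)
    row, col = net.edge_array()
    s1, s2 = _series_kernel(
        raster.astype(np.int8),
        row.astype(np.int64),
        col.astype(np.int64),
        np.ascontiguousarray(node_mask, dtype=np.bool_),
        mode == "active_only",
    )
    return ClusterSeries(s1, s2, scope=scope)


def subsystem_series(
    raster: np.ndarray,
    net: WeightedNetwork,
    parcellation: Parcellation,
    label,
    mode: str = "active_only",
) -> ClusterSeries:
    """Cluster series on the subgraph induced by the nodes carrying
    ``label`` in the parcellation."""
    if parcellation.n_nodes != net.n_nodes:
        raise ValueError("parcellation does not match the network")
    mask = parcellation.mask_of(label)  # raises for unknown label
    return cluster_series(raster, net, mode=mode, node_mask=mask, scope=str(label))


def time_average(series: ClusterSeries) -> tuple[float, float]:
    """Time-averaged sizes ``(S1, S2)``: ``S_i = (1/t_sim) sum_t S_i(t)``."""
    if series.t_sim < 1:
        raise ValueError("cannot average an empty cluster series")
    return float(series.s1.mean()), float(series.s2.mean())


def ordering_decomposition(
    series_a: ClusterSeries, series_b: ClusterSeries
) -> ClusterSeries:
    """Predicted whole-system (S1(t), S2(t)) for two fully disconnected
    subsystems: at every step the whole-system largest and second-largest
    clusters are the rank-1 and rank-2 entries of
    ``{S1_A(t), S2_A(t), S1_B(t), S2_B(t)}``.

    Exact whenever no edges cross between the subsystems; the identity is
    what turns two independently critical parts into a whole whose S2 merely
    tracks the runner-up subsystem cluster.
    """
    if series_a.t_sim != series_b.t_sim:
        raise ValueError("subsystem series must be aligned in time")
    stacked = np.stack([series_a.s1, series_a.s2, series_b.s1, series_b.s2])
    top2 = -np.partition(-stacked, 1, axis=0)[:2]
    return ClusterSeries(top2[0], top2[1], scope="predicted_whole")
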