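"""Structural integrity measures on weighted (possibly directed) graphs.

Notation: ``w_ij`` is the weight from node j to node i, the in-strength is
``w_in_i = sum_j w_ij``, the out-strength ``w_out_i = sum_j w_ji`` and the
total strength ``2w = sum_ij w_ij``.

* conductance ``h_G(S) = |cut(S, S~)| / min(vol(S), vol(S~))`` with
  ``cut = sum_{i in S, j in S~} (w_ij + w_ji)`` and ``vol(S) = sum_{i in S}
  w_out_i`` — the interconnectivity of a chosen RSN with the rest;
* modularity ``Q = (1/2w) sum_ij (w_ij - w_out_i w_in_j / 2w) delta(c_i,c_j)``
  and its ceiling ``Q_max = 1 - (1/2w) sum_ij (w_out_i w_in_j / 2w)
  delta(c_i,c_j)``; all reported modularities are ``Q / Q_max``;
* Louvain community detection (delegated to networkx, with Q evaluated by
  this module's own code) and a Pearson correlation summary with Fisher-z
  confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .networks import WeightedNetwork

__all__ = [
    "Partition",
    "strengths",
    "conductance",
    "modularity",
    "q_max",
    "q_normalized",
    "louvain_partition",
    "pearson_ci",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one community label."""

    labels: tuple

    def __init__(self, labels: Sequence) -> None:
        object.__setattr__(self, "labels", tuple(labels))
        if not self.labels:
            raise ValueError("partition must cover at least one node")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def indicator(self) -> np.ndarray:
        """Boolean ``(n, n)`` matrix of the Kronecker delta of labels."""
        arr = np.asarray(self.labels, dtype=object)
        return arr[:, None] == arr[None, :]


def strengths(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-node in- and out-strengths and the total strength ``2w``."""
    w_in = net.weights.sum(axis=1)
    w_out = net.weights.sum(axis=0)
    return w_in, w_out, float(net.weights.sum())


def conductance(net: WeightedNetwork, node_set) -> float:
    """Conductance of a node subset against its complement."""
    n = net.n_nodes
    mask = np.zeros(n, dtype=bool)
    node_set = np.asarray(list(node_set), dtype=int)
    if node_set.size == 0:
        raise ValueError("node set must be non-empty")
    mask[node_set] = True
    if mask.all():
        raise ValueError("node set must be a proper subset")
    _, w_out, _ = strengths(net)
    vol_s = float(w_out[mask].sum())
    vol_c = float(w_out[~mask].sum())
    if min(vol_s, vol_c) == 0:
        raise ValueError("conductance undefined: a side of the cut has zero volume")
    cut = float(net.weights[np.ix_(mask, ~mask)].sum() + net.weights[np.ix_(~mask, mask)].sum())
    return cut / min(vol_s, vol_c)


def modularity(net: WeightedNetwork, partition: Partition) -> float:
    """Weighted directed modularity of the given partition."""
    if partition.n_nodes != net.n_nodes:
        raise ValueError("partition does not match the network")
    w_in, w_out, two_w = strengths(net)
    if two_w == 0:
        raise ValueError("modularity undefined for a weightless network")
    delta = partition.indicator()
    null = np.outer(w_out, w_in) / two_w
    return float(((net.weights - null) * delta).sum() / two_w)


def q_max(net: WeightedNetwork, partition: Partition) -> float:
    """Maximal modularity of a perfectly mixed network with the same
    strengths: ``1 - (1/2w) sum_same-module w_out_i w_in_j / 2w``."""
    if partition.n_nodes != net.n_nodes:
        raise ValueError("partition does not match the network")
    w_in, w_out, two_w = strengths(net)
    if two_w == 0:
        raise ValueError("q_max undefined for a weightless network")
    delta = partition.indicator()
    null = np.outer(w_out, w_in) / two_w
    return float(1.0 - (null * delta).sum() / two_w)


def q_normalized(net: WeightedNetwork, partition: Partition) -> float:
    """``Q / Q_max``; equals 1 iff there is no inter-module weight."""
    return modularity(net, partition) / q_max(net, partition)


def louvain_partition(
    net: WeightedNetwork, seed: int | None = None, n_restarts: int = 10, resolution: float = 1.0
) -> Partition:
    """Best-of-``n_restarts`` Louvain community detection.

    Directed matrices are symmetrized (mean of both directions) for the
    detection step; the winning restart is selected by this module's own
    modularity evaluation, and the result is at least as modular as the
    trivial singleton and all-in-one partitions.
    """
    sym = (net.weights + net.weights.T) / 2.0
    g = nx.from_numpy_array(sym)
    ss = np.random.SeedSequence(seed)
    best: Partition | None = None
    best_q = -np.inf
    for child in ss.spawn(max(1, n_restarts)):
        restart_seed = int(child.generate_state(1)[0] % (2**31))
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=restart_seed, resolution=resolution
        )
        labels = np.empty(net.n_nodes, dtype=int)
        for c, nodes in enumerate(communities):
            labels[list(nodes)] = c
        part = Partition(labels.tolist())
        q = modularity(net, part)
        if q > best_q:
            best_q, best = q, part
    assert best is not None
    return best


def pearson_ci(x, y, confidence: float = 0.95) -> tuple[float, float, float, float]:
    """Pearson correlation with two-sided p-value and a Fisher-z confidence
    interval; raises for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high)
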