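"""Minimal artificial-stroke lesions on labelled connectomes.

Two variants, both leaving node count, parcellation validity and the
internal structure of the target RSN untouched (weights are zeroed, nodes
are never deleted):

* ``node_severity`` — select a fraction (the severity proxy) of the target
  RSN's nodes uniformly and remove all of their connections to nodes outside
  the RSN;
* ``edge_fraction`` — remove a fraction of the undirected inter-RSN
  connections chosen uniformly (a tract is one connection: both directions
  of a pair are zeroed together).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .networks import WeightedNetwork, Parcellation

__all__ = ["LesionSpec", "apply_node_severity", "apply_edge_fraction", "lesion_ensemble"]


@dataclass(frozen=True)
class LesionSpec:
    """Description of one lesion condition."""

    target_label: object
    severity: float
    variant: str = "node_severity"
    n_realizations: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must lie in [0, 1]")
        if self.variant not in ("node_severity", "edge_fraction"):
            raise ValueError(f"unknown lesion variant: {self.variant!r}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be at least 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def apply_node_severity(
    net: WeightedNetwork,
    parcellation: Parcellation,
    spec: LesionSpec,
    rng: np.random.Generator,
) -> WeightedNetwork:
    """Disconnect ``round(severity * |RSN|)`` uniformly chosen RSN nodes from
    every node outside the RSN (both directions zeroed); intra-RSN and
    non-RSN weights are bit-identical to the input."""
    if parcellation.n_nodes != net.n_nodes:
        raise ValueError("parcellation does not match the network")
    rsn = parcellation.nodes_of(spec.target_label)
    k = _round_half_up(spec.severity * rsn.size)
    if k == 0:
        return net
    chosen = rng.choice(rsn, size=k, replace=False)
    outside = np.setdiff1d(np.arange(net.n_nodes), rsn)
    w = net.weights.copy()
    w[np.ix_(chosen, outside)] = 0.0
    w[np.ix_(outside, chosen)] = 0.0
    return WeightedNetwork(w, directed=net.directed, node_ids=net.node_ids)


def apply_edge_fraction(
    net: WeightedNetwork,
    parcellation: Parcellation,
    spec: LesionSpec,
    rng: np.random.Generator,
) -> WeightedNetwork:
    """Zero ``round(severity * |cut|)`` undirected inter-RSN connections
    chosen uniformly from the cut between the target RSN and the rest."""
    if parcellation.n_nodes != net.n_nodes:
        raise ValueError("parcellation does not match the network")
    mask = parcellation.mask_of(spec.target_label)
    sup = net.support()
    row, col = np.nonzero(np.triu(sup, k=1))
    crossing = mask[row] != mask[col]
    cut_row, cut_col = row[crossing], col[crossing]
    k = _round_half_up(spec.severity * cut_row.size)
    if k == 0:
        return net
    pick = rng.choice(cut_row.size, size=k, replace=False)
    w = net.weights.copy()
    w[cut_row[pick], cut_col[pick]] = 0.0
    w[cut_col[pick], cut_row[pick]] = 0.0
    return WeightedNetwork(w, directed=net.directed, node_ids=net.node_ids)


_VARIANTS = {"node_severity": apply_node_severity, "edge_fraction": apply_edge_fraction}


def apply_lesion(
    net: WeightedNetwork,
    parcellation: Parcellation,
    spec: LesionSpec,
    rng: np.random.Generator,
) -> WeightedNetwork:
    """Dispatch on ``spec.variant``."""
    return _VARIANTS[spec.variant](net, parcellation, spec, rng)


def lesion_ensemble(
    net: WeightedNetwork,
    parcellation: Parcellation,
    spec: LesionSpec,
    downstream: Callable[[WeightedNetwork, int, int], dict],
) -> tuple[pd.DataFrame, pd.Series]:
    """Run ``downstream(lesioned_net, realization_index, sub_seed)`` on each
    of ``spec.n_realizations`` independently seeded lesion realizations.

    ``downstream`` returns a flat dict of scalars; the per-realization rows
    and their mean are returned.  Results reported in the study-style
    analyses are ensemble means over such realizations.
    """
    ss = np.random.SeedSequence(spec.seed)
    rows = []
    for r, child in enumerate(ss.spawn(spec.n_realizations)):
        lesion_seed, analysis_seed = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        rng = np.random.default_rng(lesion_seed)
        lesioned = apply_lesion(net, parcellation, spec, rng)
        try:
            out = downstream(lesioned, r, analysis_seed)
        except Exception as exc:
            raise RuntimeError(f"downstream analysis failed at realization {r}") from exc
        rows.append({"realization": r, **out})
    frame = pd.DataFrame(rows)
    mean = frame.drop(columns="realization").mean()
    return frame, mean
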