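"""Single-flip Metropolis Monte Carlo for the Ising model on unit-weight
networks (square lattices, divided lattices).

The energy of a spin configuration ``s in {-1, +1}^N`` on the binary support
of the network is ``E = -J * sum_{bonds {i,j}} s_i s_j`` with each unordered
bond counted once — the convention under which the infinite square lattice
orders at ``T_c = 2 / ln(1 + sqrt(2)) ≈ 2.269``.  A sweep proposes ``N``
single-spin flips, each accepted with probability ``min(exp(-dE/T), 1)``.

``metropolis_sweep`` is the numpy reference; ``run_ising`` drives a compiled
kernel with identical acceptance semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix

from .networks import WeightedNetwork, Parcellation

__all__ = [
    "IsingParams",
    "SpinRaster",
    "energy",
    "delta_energy",
    "metropolis_sweep",
    "run_ising",
    "temperature_sweep",
    "ONSAGER_TC",
]

#: Exact critical temperature of the infinite 2-D square-lattice Ising model,
#: 2 / ln(1 + sqrt(2)).
ONSAGER_TC = 2.0 / np.log(1.0 + np.sqrt(2.0))


@dataclass(frozen=True)
class IsingParams:
    """Parameters of one Metropolis run.

    ``p_minus_init`` is the probability that an initial spin is -1 (0.75 by
    default, a mostly-down start); ``proposal_order`` chooses whether the N
    per-sweep proposals pick sites uniformly at random (default) or in
    raster order.
    """

    temperature: float
    coupling: float = 1.0
    t_max: int = 5000
    t_init: int = 200
    p_minus_init: float = 0.75
    seed: int | None = None
    proposal_order: str = "random"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 <= self.p_minus_init <= 1:
            raise ValueError("p_minus_init must be a probability")
        if self.t_max <= self.t_init:
            raise ValueError("t_max must exceed t_init")
        if self.proposal_order not in ("random", "sequential"):
            raise ValueError("proposal_order must be 'random' or 'sequential'")


@dataclass(frozen=True)
class SpinRaster:
    """``n_sites x t_sim`` record of spins, entries in {-1, +1}."""

    spins: np.ndarray
    t_init: int

    def __post_init__(self) -> None:
        if self.spins.ndim != 2:
            raise ValueError("spin raster must be 2-D (sites x time)")
        if not np.isin(self.spins, (-1, 1)).all():
            raise ValueError("spins must be -1 or +1")

    @property
    def n_sites(self) -> int:
        return self.spins.shape[0]

    @property
    def t_sim(self) -> int:
        return self.spins.shape[1]


def energy(spins: np.ndarray, net: WeightedNetwork, J: float = 1.0) -> float:
    """Total energy ``-J * sum over unordered bonds of s_i s_j`` on the
    binary support of the network."""
    spins = np.asarray(spins)
    if spins.shape != (net.n_nodes,):
        raise ValueError("spin vector length must match the network")
    row, col = net.edge_array()
    return float(-J * np.sum(spins[row] * spins[col]))


def delta_energy(
    spins: np.ndarray, site: int, net: WeightedNetwork, J: float = 1.0
) -> float:
    """Energy change of flipping ``site``: ``2 J s_site sum_neigh s_j``;
    identical to ``energy(after) - energy(before)``."""
    spins = np.asarray(spins)
    if not 0 <= site < net.n_nodes:
        raise IndexError(f"site {site} out of range for {net.n_nodes} nodes")
    neigh = net.support()[site]
    return float(2.0 * J * spins[site] * spins[neigh].sum())


def metropolis_sweep(
    spins: np.ndarray,
    net: WeightedNetwork,
    params: IsingParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One sweep = ``n`` proposed single-site flips, each accepted with
    probability ``min(exp(-dE/T), 1)``.  Returns a new spin vector."""
    spins = np.asarray(spins).copy()
    n = net.n_nodes
    support = net.support()
    if params.proposal_order == "random":
        sites = rng.integers(0, n, size=n)
    else:
        sites = np.arange(n)
    for site in sites:
        d_e = 2.0 * params.coupling * spins[site] * spins[support[site]].sum()
        if d_e <= 0 or rng.random() < np.exp(-d_e / params.temperature):
            spins[site] = -spins[site]
    return spins


@njit(cache=True)
def _ising_kernel(indptr, indices, spins, T, J, t_max, t_init, seed, random_order):  # pragma: no cover
    np.random.seed(seed)
    n = spins.shape[0]
    t_sim = t_max - t_init
    raster = np.empty((n, t_sim), dtype=np.int8)
    for t in range(t_max):
        for k in range(n):
            site = np.random.randint(0, n) if random_order else k
            field = 0
            for p in range(indptr[site], indptr[site + 1]):
                field += spins[indices[p]]
            d_e = 2.0 * J * spins[site] * field
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / T):
                spins[site] = -spins[site]
        if t >= t_init:
            raster[:, t - t_init] = spins
    return raster


def run_ising(net: WeightedNetwork, params: IsingParams) -> SpinRaster:
    """Full Metropolis run; records the configuration after every sweep past
    the discarded ``t_init`` transient.  Fixed seed gives a bit-identical
    raster."""
    n = net.n_nodes
    ss = np.random.SeedSequence(params.seed)
    init_ss, dyn_ss = ss.spawn(2)
    rng = np.random.default_rng(init_ss)
    spins = np.where(rng.random(n) < params.p_minus_init, -1, 1).astype(np.int8)

    adj = csr_matrix(net.support())
    kernel_seed = int(dyn_ss.generate_state(1)[0] % (2**31))
    raster = _ising_kernel(
        adj.indptr,
        adj.indices,
        spins,
        float(params.temperature),
        float(params.coupling),
        int(params.t_max),
        int(params.t_init),
        kernel_seed,
        params.proposal_order == "random",
    )
    return SpinRaster(raster, params.t_init)


def temperature_sweep(
    net: WeightedNetwork,
    temperatures: Sequence[float],
    params_base: IsingParams,
    parcellation: Parcellation | None = None,
    subsystem_labels: Sequence | None = None,
):
    """One independent Metropolis run per temperature; assembles S1/S2 (and
    per-subsystem) curves into a :class:`~criticonn.indicators.SweepResult`.
    The default protocol is 30 equally spaced temperatures in [0.01, 4.5]."""
    from . import indicators as ind
    from . import clusters as cl

    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size < 2:
        raise ValueError("temperature grid needs at least 2 ascending values")
    if np.any(np.diff(temperatures) <= 0):
        raise ValueError("temperature grid must be strictly ascending")

    ss = np.random.SeedSequence(params_base.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(temperatures.size)]

    if subsystem_labels is None:
        subsystem_labels = ()
    elif parcellation is None:
        raise ValueError("subsystem_labels requires a parcellation")

    curves: dict[str, list[float]] = {k: [] for k in ("S1", "S2", "var_S1", "abs_magnetization")}
    for lab in subsystem_labels:
        curves[f"S1[{lab}]"] = []
        curves[f"S2[{lab}]"] = []
    series_per_point = []

    for T, sub_seed in zip(temperatures, sub_seeds):
        params = replace(params_base, temperature=float(T), seed=sub_seed)
        raster = run_ising(net, params)
        series = cl.cluster_series(raster.spins, net, mode="same_value")
        s1_bar, s2_bar = cl.time_average(series)
        curves["S1"].append(s1_bar)
        curves["S2"].append(s2_bar)
        curves["var_S1"].append(ind.var_largest_cluster(series))
        curves["abs_magnetization"].append(float(np.abs(raster.spins.sum(axis=0)).mean()))
        for lab in subsystem_labels:
            sub = cl.subsystem_series(raster.spins, net, parcellation, lab, mode="same_value")
            sub1, sub2 = cl.time_average(sub)
            curves[f"S1[{lab}]"].append(sub1)
            curves[f"S2[{lab}]"].append(sub2)
        series_per_point.append(series)

    return ind.SweepResult(
        grid=temperatures,
        control="temperature",
        curves={k: np.array(v) for k, v in curves.items()},
        cluster_series=series_per_point,
        metadata={
            "master_seed": params_base.seed,
            "sub_seeds": sub_seeds,
            "t_max": params_base.t_max,
            "t_init": params_base.t_init,
            "coupling": params_base.coupling,
        },
    )
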