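"""Greenberg–Hastings excitable dynamics on weighted networks.

Three node states: inactive (I=0), active (A=1), refractory (R=2).  At each
discrete time step, synchronously over all nodes,

* ``A -> R`` always;
* ``R -> I`` with probability ``r2``;
* ``I -> A`` deterministically if the summed weight of active in-neighbours
  exceeds the activation threshold ``T`` (strict inequality), else
  spontaneously with probability ``r1``.

The activation threshold is the control parameter: small ``T`` gives a
supercritical high-activity phase, large ``T`` a subcritical quiescent phase,
with a dynamical phase transition in between whose location on in-strength-
normalized connectomes is predicted by the mean-field estimate implemented in
:mod:`criticonn.indicators`.

``gh_step`` is the pure-numpy reference semantics; ``run_gh`` executes the
same rules in a compiled kernel for long rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix

from .networks import WeightedNetwork, Parcellation

__all__ = [
    "GHParams",
    "ActivityRaster",
    "default_rates",
    "gh_step",
    "run_gh",
    "threshold_sweep",
]

INACTIVE, ACTIVE, REFRACTORY = 0, 1, 2


@dataclass(frozen=True)
class GHParams:
    """Parameters of a single excitable-automaton run.

    ``r1`` (spontaneous activation) and ``r2`` (refractory release) are small
    probabilities setting the system's timescale; the canonical choices are
    ``r1 = 2/N`` and ``r2 = r1**0.2`` (see :func:`default_rates`).
    """

    threshold: float
    r1: float
    r2: float
    t_max: int = 10_000
    t_init: int = 200
    init_active_frac: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        for name in ("r1", "r2"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not 0 < self.init_active_frac < 1:
            raise ValueError("init_active_frac must lie strictly in (0, 1)")
        if self.t_max <= self.t_init:
            raise ValueError("t_max must exceed t_init")


@dataclass(frozen=True)
class ActivityRaster:
    """Post-transient activity record of one run.

    ``states`` is the conflated ``n x t_sim`` binary matrix (1 = active,
    0 = inactive or refractory); ``raw`` optionally retains the three-state
    record (0/1/2).
    """

    states: np.ndarray
    t_init: int
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.states.ndim != 2:
            raise ValueError("raster must be 2-D (nodes x time)")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("conflated raster entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.states.shape[0]

    @property
    def t_sim(self) -> int:
        return self.states.shape[1]


def default_rates(n: int) -> tuple[float, float]:
    """Canonical transition rates for an ``n``-node network:
    ``r1 = 2/n``, ``r2 = r1**0.2``."""
    if n < 1:
        raise ValueError("node count must be positive")
    r1 = 2.0 / n
    return r1, r1**0.2


def gh_step(
    state: np.ndarray,
    net: WeightedNetwork,
    params: GHParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous update; all three transitions read the start-of-step
    state, so a node activated within the step does not excite its neighbours
    until the next step."""
    state = np.asarray(state)
    if state.shape != (net.n_nodes,):
        raise ValueError("state length must match the network")
    active = state == ACTIVE
    drive = net.weights @ active.astype(float)

    new = np.empty_like(state)
    new[active] = REFRACTORY
    refr = state == REFRACTORY
    new[refr] = np.where(rng.random(int(refr.sum())) < params.r2, INACTIVE, REFRACTORY)
    inact = state == INACTIVE
    fire = drive[inact] > params.threshold
    spont = rng.random(int(inact.sum())) < params.r1
    new[inact] = np.where(fire | spont, ACTIVE, INACTIVE)
    return new


@njit(cache=True)
def _gh_kernel(indptr, indices, data, threshold, r1, r2, t_max, t_init, state, seed):  # pragma: no cover
    np.random.seed(seed)
    n = state.shape[0]
    t_sim = t_max - t_init
    raw = np.empty((n, t_sim), dtype=np.int8)
    drive = np.zeros(n)
    new = np.empty(n, dtype=np.int8)
    for t in range(t_max):
        drive[:] = 0.0
        for i in range(n):
            if state[i] == 1:
                for p in range(indptr[i], indptr[i + 1]):
                    drive[indices[p]] += data[p]
        for i in range(n):
            s = state[i]
            if s == 1:
                new[i] = 2
            elif s == 2:
                new[i] = 0 if np.random.random() < r2 else 2
            else:
                if drive[i] > threshold or np.random.random() < r1:
                    new[i] = 1
                else:
                    new[i] = 0
        state[:] = new
        if t >= t_init:
            raw[:, t - t_init] = state
    return raw


def run_gh(
    net: WeightedNetwork, params: GHParams, keep_raw: bool = False
) -> ActivityRaster:
    """Run the automaton for ``t_max`` steps, discard the first ``t_init``,
    and return the conflated (refractory -> 0) raster.

    The run starts with ``ceil(init_active_frac * n)`` nodes active (chosen
    uniformly without replacement) and the rest inactive.  Fixed seed gives a
    bit-identical raster.
    """
    n = net.n_nodes
    ss = np.random.SeedSequence(params.seed)
    init_ss, dyn_ss = ss.spawn(2)
    rng = np.random.default_rng(init_ss)
    n_active = math.ceil(params.init_active_frac * n)
    state = np.zeros(n, dtype=np.int8)
    state[rng.choice(n, size=n_active, replace=False)] = ACTIVE

    # CSR of outgoing influence: node j's active state adds w_ij to drive[i].
    out = csr_matrix(net.weights.T)
    kernel_seed = int(dyn_ss.generate_state(1)[0] % (2**31))
    raw = _gh_kernel(
        out.indptr,
        out.indices,
        out.data,
        float(params.threshold),
        float(params.r1),
        float(params.r2),
        int(params.t_max),
        int(params.t_init),
        state,
        kernel_seed,
    )
    conflated = (raw == ACTIVE).astype(np.int8)
    return ActivityRaster(conflated, params.t_init, raw=raw if keep_raw else None)


def threshold_sweep(
    net: WeightedNetwork,
    thresholds: Sequence[float],
    params_base: GHParams,
    parcellation: Parcellation | None = None,
    subsystem_labels: Sequence | None = None,
):
    """Run one independent automaton realization per threshold and assemble
    indicator and cluster curves into a :class:`~criticonn.indicators.SweepResult`.

    Each grid point gets a fresh sub-seed spawned from ``params_base.seed``,
    so results are reproducible and independent of execution order.
    """
    from . import indicators as ind
    from . import clusters as cl

    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 2:
        raise ValueError("threshold grid needs at least 2 ascending values")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("threshold grid must be strictly ascending")

    ss = np.random.SeedSequence(params_base.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(thresholds.size)]

    if subsystem_labels is None:
        subsystem_labels = ()
    elif parcellation is None:
        raise ValueError("subsystem_labels requires a parcellation")

    curves: dict[str, list[float]] = {
        k: [] for k in ("S1", "S2", "mean_activity", "sigma_A", "rho1", "var_S1")
    }
    for lab in subsystem_labels:
        curves[f"S1[{lab}]"] = []
        curves[f"S2[{lab}]"] = []
    series_per_point = []

    for thr, sub_seed in zip(thresholds, sub_seeds):
        params = replace(params_base, threshold=float(thr), seed=sub_seed)
        raster = run_gh(net, params)
        series = cl.cluster_series(raster.states, net, mode="active_only")
        a_t = ind.total_activity(raster)
        mean_a, sigma_a = ind.activity_stats(a_t)
        s1_bar, s2_bar = cl.time_average(series)
        curves["S1"].append(s1_bar)
        curves["S2"].append(s2_bar)
        curves["mean_activity"].append(mean_a)
        curves["sigma_A"].append(sigma_a)
        curves["rho1"].append(ind.autocorr1(a_t))
        curves["var_S1"].append(ind.var_largest_cluster(series))
        for lab in subsystem_labels:
            sub = cl.subsystem_series(raster.states, net, parcellation, lab)
            sub1, sub2 = cl.time_average(sub)
            curves[f"S1[{lab}]"].append(sub1)
            curves[f"S2[{lab}]"].append(sub2)
        series_per_point.append(series)

    return ind.SweepResult(
        grid=thresholds,
        control="threshold",
        curves={k: np.array(v) for k, v in curves.items()},
        cluster_series=series_per_point,
        metadata={
            "master_seed": params_base.seed,
            "sub_seeds": sub_seeds,
            "t_max": params_base.t_max,
            "t_init": params_base.t_init,
            "r1": params_base.r1,
            "r2": params_base.r2,
        },
    )
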