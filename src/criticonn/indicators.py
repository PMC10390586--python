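"""Scalar criticality indicators and sweep-curve summaries.

Given a binary activity raster and its cluster series, the package tracks:
total activity ``A(t)`` with mean and population standard deviation, the
lag-1 autocorrelation ``rho(1)`` of ``A(t)``, the variance of the largest
cluster size, the area ``I2`` under the S2 curve, interior-vs-boundary peak
location (a boundary argmax operationalizes the "loss of peak" regime), the
mean-field critical threshold of the excitable dynamics, and the
normalizations used when comparing lesioned systems to their baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import WeightedNetwork
from .clusters import ClusterSeries

__all__ = [
    "IndicatorCurve",
    "SweepResult",
    "total_activity",
    "activity_stats",
    "autocorr1",
    "var_largest_cluster",
    "area_under_s2",
    "peak_location",
    "mean_field_tc",
    "normalize_to_max",
    "normalized_change",
]


@dataclass(frozen=True)
class IndicatorCurve:
    """One indicator as a function of the control parameter."""

    grid: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise ValueError("grid and values must be 1-D and aligned")
        if grid.size >= 2 and np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)


@dataclass
class SweepResult:
    """Bundle of indicator curves sharing one control-parameter grid.

    ``control`` is ``"threshold"`` (excitable dynamics) or ``"temperature"``
    (Ising).  ``curves`` maps indicator names to value arrays; per-grid-point
    :class:`ClusterSeries` are retained for momentary-cluster analyses.
    """

    grid: np.ndarray
    control: str
    curves: dict
    cluster_series: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for name, vals in self.curves.items():
            if len(vals) != self.grid.size:
                raise ValueError(f"curve {name!r} does not match the grid length")

    def curve(self, name: str) -> IndicatorCurve:
        return IndicatorCurve(self.grid, np.asarray(self.curves[name]), name=name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.control: self.grid})
        for name, vals in self.curves.items():
            df[name] = np.asarray(vals)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def save_metadata(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def total_activity(raster) -> np.ndarray:
    """Total activity ``A(t) = sum_i s_i(t)`` of a conflated raster (accepts
    an :class:`~criticonn.gh_dynamics.ActivityRaster` or a plain array)."""
    states = getattr(raster, "states", raster)
    states = np.asarray(states)
    if states.ndim != 2 or states.size == 0:
        raise ValueError("raster must be a non-empty (n_nodes, t_sim) matrix")
    return states.sum(axis=0).astype(float)


def activity_stats(a: np.ndarray) -> tuple[float, float]:
    """Mean activity and its population standard deviation (divisor
    ``t_sim``, not ``t_sim - 1``)."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("empty activity series")
    return float(a.mean()), float(a.std(ddof=0))


def autocorr1(a: np.ndarray) -> float:
    """Lag-1 autocorrelation of the raw series with overall mean and
    population variance:
    ``sum_{t<T}(A_t - mean)(A_{t+1} - mean) / sum_t (A_t - mean)^2``.
    Returns 0 for a zero-variance series."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("autocorrelation needs at least 2 samples")
    d = a - a.mean()
    denom = np.dot(d, d)
    if denom == 0:
        return 0.0
    return float(np.dot(d[:-1], d[1:]) / denom)


def var_largest_cluster(series: ClusterSeries) -> float:
    """Population variance of the momentary largest-cluster size."""
    return float(np.asarray(series.s1, dtype=float).var(ddof=0))


def area_under_s2(curve: IndicatorCurve) -> float:
    """Trapezoidal area ``I2 = integral of S2 over the sampled grid``; the
    integration limits are the grid limits, so comparisons across conditions
    must share one grid."""
    if curve.grid.size < 2:
        raise ValueError("need at least 2 grid points to integrate")
    return float(np.trapezoid(curve.values, curve.grid))


def peak_location(curve: IndicatorCurve) -> tuple[float, bool]:
    """Grid argmax of the curve and whether it is interior.

    A boundary argmax (first or last grid point) flags the loss-of-peak
    regime of a heavily lesioned or divided system.  Ties resolve to the
    smaller grid value.
    """
    if curve.grid.size < 3:
        raise ValueError("need at least 3 grid points to locate a peak")
    i = int(np.argmax(curve.values))
    return float(curve.grid[i]), bool(0 < i < curve.grid.size - 1)


def mean_field_tc(net: WeightedNetwork, r2: float) -> float:
    """Mean-field estimate of the excitable dynamics' critical threshold:
    ``T_c = <w_in> * r2 / (1 + 2 r2)`` with ``<w_in>`` the mean in-strength."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must be a probability")
    mean_w_in = float(net.weights.sum(axis=1).mean())
    return mean_w_in * r2 / (1.0 + 2.0 * r2)


def normalize_to_max(curve: IndicatorCurve) -> IndicatorCurve:
    """Scale a curve by its maximum so the largest value maps to exactly 1."""
    m = curve.values.max()
    if not m > 0:
        raise ValueError("cannot normalize a curve with non-positive maximum")
    return IndicatorCurve(curve.grid, curve.values / m, name=curve.name)


def normalized_change(value: float, baseline: float) -> float:
    """Relative change ``(A - A0) / A0`` against the unmodified system; zero
    means indistinguishable from baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return (value - baseline) / baseline
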