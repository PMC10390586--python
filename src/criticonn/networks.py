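"""Network construction, normalization and I/O.

All dynamics in this package run on a :class:`WeightedNetwork`: an ``n x n``
non-negative weight matrix with the convention that ``weights[i, j]`` is the
weight of the directed connection *from node j to node i* (row = receiver).
The module generates the three network families used throughout —
Watts–Strogatz small-world graphs with exponentially distributed weights,
modular connectome-like networks with resting-state-network (RSN) labels, and
(optionally divided) square lattices — and reads/writes them as plain text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "WeightedNetwork",
    "Parcellation",
    "LatticeSpec",
    "generate_ws_network",
    "generate_modular_connectome",
    "default_connectome",
    "normalize_in_strength",
    "build_lattice",
    "read_network",
    "write_network",
    "read_parcellation",
    "write_parcellation",
]

#: Canonical resting-state-network names for the default 8-module connectome.
DEFAULT_RSN_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
    "auditory",
)

#: Module sizes of the default synthetic connectome (sum = 998; the auditory
#: module has 119 nodes, the size used as the small disconnected subsystem).
DEFAULT_MODULE_SIZES = (150, 140, 130, 125, 120, 110, 104, 119)


@dataclass(frozen=True)
class WeightedNetwork:
    """A weighted, possibly directed network.

    Parameters
    ----------
    weights
        ``(n, n)`` array; ``weights[i, j]`` is the weight of the connection
        from node ``j`` to node ``i``.  The diagonal is zero by convention.
    directed
        If ``False`` the weight matrix must be symmetric.
    node_ids
        Ordered node labels; defaults to ``0..n-1``.
    """

    weights: np.ndarray
    directed: bool = False
    node_ids: tuple = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("diagonal (self-loop) weights must be zero")
        if not self.directed and not np.array_equal(w, w.T):
            raise ValueError("undirected network requires a symmetric matrix")
        object.__setattr__(self, "weights", w)
        if not self.node_ids:
            object.__setattr__(self, "node_ids", tuple(range(w.shape[0])))
        elif len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def support(self) -> np.ndarray:
        """Undirected binary support ``w_ij + w_ji > 0`` used for cluster
        connectivity (structural adjacency, not flow)."""
        return (self.weights + self.weights.T) > 0

    def edge_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Each unordered supported edge once, as ``(row, col)`` index arrays
        with ``row < col``."""
        a = np.triu(self.support(), k=1)
        return np.nonzero(a)


@dataclass(frozen=True)
class Parcellation:
    """Assignment of every node to exactly one module (RSN) label."""

    labels: tuple

    def __init__(self, labels: Sequence) -> None:
        labels = tuple(labels)
        if not labels:
            raise ValueError("parcellation must label at least one node")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def label_set(self) -> tuple:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def nodes_of(self, label) -> np.ndarray:
        """Indices of the nodes carrying ``label``."""
        if label not in self.labels:
            raise ValueError(f"unknown parcellation label: {label!r}")
        return np.array([i for i, lab in enumerate(self.labels) if lab == label])

    def mask_of(self, label) -> np.ndarray:
        mask = np.zeros(len(self.labels), dtype=bool)
        mask[self.nodes_of(label)] = True
        return mask


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of a (possibly divided) nonperiodic square lattice.

    ``equal_halves`` cuts the lattice into two ``rows x cols/2`` rectangles;
    ``central_patch`` disconnects a ``patch_side x patch_side`` square patch
    (subsystem B) centered in the lattice from its complement (subsystem A).
    """

    rows: int
    cols: int
    division: Literal["none", "equal_halves", "central_patch"] = "none"
    patch_side: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.division not in ("none", "equal_halves", "central_patch"):
            raise ValueError(f"unknown division: {self.division!r}")
        if self.division == "equal_halves" and self.cols % 2:
            raise ValueError("equal_halves requires an even number of columns")
        if self.division == "central_patch":
            if not (0 < self.patch_side < min(self.rows, self.cols)):
                raise ValueError("patch_side must be positive and smaller than the lattice")
            r0 = (self.rows - self.patch_side) // 2
            c0 = (self.cols - self.patch_side) // 2
            if r0 < 1 or c0 < 1 or r0 + self.patch_side > self.rows - 1 or c0 + self.patch_side > self.cols - 1:
                raise ValueError("central patch must be strictly interior to the lattice")

    @property
    def n_sites(self) -> int:
        return self.rows * self.cols


def generate_ws_network(
    n: int, k: int, pi: float, lam: float = 12.5, seed: int | None = None
) -> WeightedNetwork:
    """Watts–Strogatz small-world network with exponential edge weights.

    Nodes start on a ring, each connected to its ``k`` nearest neighbours
    (``k/2`` on each side); every edge is rewired to a random node with
    probability ``pi``.  Edge weights are i.i.d. draws from
    ``p(w) = lam * exp(-lam * w)``, mimicking the weight distribution of
    empirical human connectomes (``lam = 12.5``).

    The edge count is exactly ``n*k/2`` for any ``pi``.
    """
    if n < 3:
        raise ValueError("n must be at least 3")
    if k % 2 or not (0 < k < n):
        raise ValueError("k must be even, positive and smaller than n")
    if not 0 <= pi <= 1:
        raise ValueError("rewiring probability must lie in [0, 1]")
    if lam <= 0:
        raise ValueError("exponential rate lam must be positive")
    ss = np.random.SeedSequence(seed)
    nx_seed, w_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    g = nx.watts_strogatz_graph(n, k, pi, seed=nx_seed)
    rng = np.random.default_rng(w_seed)
    w = np.zeros((n, n))
    for u, v in sorted(g.edges()):
        w[u, v] = w[v, u] = rng.exponential(1.0 / lam)
    return WeightedNetwork(w, directed=False)


def generate_modular_connectome(
    n: int,
    module_sizes: Sequence[int],
    mean_degree_in: float,
    mean_degree_out: float,
    lam: float = 12.5,
    seed: int | None = None,
    module_names: Sequence | None = None,
) -> tuple[WeightedNetwork, Parcellation]:
    """Synthetic modular connectome: a weighted stochastic block network.

    Within-module edges appear with probability giving an expected
    within-module degree of ``mean_degree_in``; between-module edges give an
    expected between-module degree of ``mean_degree_out``.  Every module is
    made internally connected (a random spanning chain is added if the block
    sample leaves it fragmented).  Weights are exponential(``lam``).
    """
    module_sizes = list(module_sizes)
    if sum(module_sizes) != n:
        raise ValueError(f"module sizes {module_sizes} do not sum to n={n}")
    if any(s < 2 for s in module_sizes):
        raise ValueError("every module needs at least 2 nodes")
    if not mean_degree_in > mean_degree_out > 0:
        raise ValueError("require mean_degree_in > mean_degree_out > 0")
    if module_names is None:
        module_names = [f"module_{i}" for i in range(len(module_sizes))]
    if len(module_names) != len(module_sizes):
        raise ValueError("module_names must match module_sizes in length")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels: list = []
    bounds = np.cumsum([0] + module_sizes)
    for name, size in zip(module_names, module_sizes):
        labels.extend([name] * size)

    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    block = np.repeat(np.arange(len(module_sizes)), module_sizes)
    same = block[iu] == block[ju]
    # Bernoulli edge probabilities targeting the requested expected degrees.
    sizes_arr = np.array(module_sizes)
    p_in_per_block = np.minimum(mean_degree_in / np.maximum(sizes_arr - 1, 1), 1.0)
    p_out = min(mean_degree_out / max(n - sizes_arr.mean(), 1), 1.0)
    p_edge = np.where(same, p_in_per_block[block[iu]], p_out)
    keep = rng.random(iu.size) < p_edge
    wvals = rng.exponential(1.0 / lam, size=int(keep.sum()))
    w[iu[keep], ju[keep]] = wvals
    w[ju[keep], iu[keep]] = wvals

    # Guarantee internal connectivity of every module.
    for m, name in enumerate(module_names):
        lo, hi = bounds[m], bounds[m + 1]
        idx = np.arange(lo, hi)
        sub = w[np.ix_(idx, idx)] > 0
        n_comp, comp = _components(sub)
        while n_comp > 1:
            a = rng.choice(idx[comp == 0])
            b = rng.choice(idx[comp != 0])
            w[a, b] = w[b, a] = rng.exponential(1.0 / lam)
            sub = w[np.ix_(idx, idx)] > 0
            n_comp, comp = _components(sub)

    return WeightedNetwork(w, directed=False), Parcellation(labels)


def _components(adj_bool: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    return connected_components(csr_matrix(adj_bool), directed=False)


def default_connectome(seed: int | None = None) -> tuple[WeightedNetwork, Parcellation]:
    """The package's default Hagmann-like synthetic connectome.

    998 nodes in 8 RSN-labelled modules (the ``auditory`` module has 119
    nodes), mean within-module degree 24, between-module degree 10,
    exponential(12.5) weights.
    """
    return generate_modular_connectome(
        n=998,
        module_sizes=DEFAULT_MODULE_SIZES,
        mean_degree_in=24.0,
        mean_degree_out=10.0,
        lam=12.5,
        seed=seed,
        module_names=DEFAULT_RSN_NAMES,
    )


def normalize_in_strength(net: WeightedNetwork) -> WeightedNetwork:
    """Homeostatic normalization: rescale each node's incoming weights to
    unit in-strength, ``w~_ij = w_ij / w_in_i``.

    Equalizes excitability across nodes; the output is generally asymmetric
    even for symmetric input, so it is flagged directed.
    """
    w_in = net.weights.sum(axis=1)
    zero = np.nonzero(w_in == 0)[0]
    if zero.size:
        raise ValueError(
            f"cannot normalize: node(s) {zero.tolist()} have zero in-strength"
        )
    return WeightedNetwork(net.weights / w_in[:, None], directed=True, node_ids=net.node_ids)


def build_lattice(spec: LatticeSpec) -> tuple[WeightedNetwork, Parcellation]:
    """Nonperiodic 4-neighbour square lattice with unit weights.

    Site ``(r, c)`` maps to node index ``r * cols + c``.  For a divided
    lattice all bonds crossing the division are removed and the parcellation
    labels the two parts ``"A"`` and ``"B"`` (B is the right half or the
    central patch); an undivided lattice is labelled ``"A"`` throughout.
    """
    rows, cols = spec.rows, spec.cols
    n = spec.n_sites
    idx = np.arange(n).reshape(rows, cols)
    w = np.zeros((n, n))

    right = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    down = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    edges = np.concatenate([right, down], axis=0)

    labels = np.full(n, "A", dtype=object)
    if spec.division == "equal_halves":
        half = cols // 2
        labels[idx[:, half:].ravel()] = "B"
    elif spec.division == "central_patch":
        s = spec.patch_side
        r0 = (rows - s) // 2
        c0 = (cols - s) // 2
        labels[idx[r0 : r0 + s, c0 : c0 + s].ravel()] = "B"

    if spec.division != "none":
        same = labels[edges[:, 0]] == labels[edges[:, 1]]
        edges = edges[same]

    w[edges[:, 0], edges[:, 1]] = 1.0
    w[edges[:, 1], edges[:, 0]] = 1.0
    return WeightedNetwork(w, directed=False), Parcellation(labels.tolist())


# ---------------------------------------------------------------------------
# Text I/O: dense matrices, weighted edge lists, parcellation tables
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"^[+-]?\d+$")

def write_network(net: WeightedNetwork, path: str | Path, fmt: str = "matrix") -> None:
    """Write a network as a dense matrix (``fmt="matrix"``) or a 3-column
    tab-separated weighted edge list (``fmt="edgelist"``, 0-based indices,
    each directed entry once; symmetric matrices emit both directions)."""
    path = Path(path)
    if fmt == "matrix":
        np.savetxt(path, net.weights, fmt="%.17g")
    elif fmt == "edgelist":
        i, j = np.nonzero(net.weights)
        with open(path, "w") as fh:
            fh.write("# source\ttarget\tweight\n")
            for a, b in zip(i, j):
                # source = sender j, target = receiver i
                fh.write(f"{b}\t{a}\t{net.weights[a, b]:.17g}\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_network(
    path: str | Path, directed: bool | None = None, fmt: str = "auto"
) -> WeightedNetwork:
    """Read a network from a dense matrix file (whitespace or commas) or a
    3-column weighted edge list (source, target, weight; 0-based indices).

    With ``fmt="auto"`` a file is treated as an edge list when every row has
    exactly three fields and the first two fields of every row are integer
    literals with no decimal point; pass ``fmt`` explicitly for the ambiguous
    3x3 integer-matrix corner case.  Raises ``ValueError`` naming the
    offending line for non-square matrices, negative weights or nonzero
    self-loops.
    """
    if fmt not in ("auto", "matrix", "edgelist"):
        raise ValueError(f"unknown format: {fmt!r}")
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        raw_lines = fh.readlines()
    for lineno, line in enumerate(raw_lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append((lineno, re.split(r"[,\s]+", line)))
    if not rows:
        raise ValueError(f"{path}: empty network file")

    if fmt == "auto":
        is_edgelist = all(
            len(r) == 3 and _INT_RE.match(r[0]) and _INT_RE.match(r[1]) for _, r in rows
        ) and (len(rows) != 3 or any(float(r[2]) != round(float(r[2])) for _, r in rows))
    else:
        is_edgelist = fmt == "edgelist"

    if is_edgelist:
        try:
            triples = [(int(r[0]), int(r[1]), float(r[2]), ln) for ln, r in rows]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed edge list: {exc}") from exc
        n = max(max(s, t) for s, t, _, _ in triples) + 1
        w = np.zeros((n, n))
        for s, t, wt, ln in triples:
            if s == t:
                raise ValueError(f"{path}:{ln}: self-loop on node {s} (diagonal must be zero)")
            if wt < 0:
                raise ValueError(f"{path}:{ln}: negative weight {wt}")
            w[t, s] = wt  # receiver row convention
    else:
        mat = []
        width = None
        for ln, r in rows:
            vals = [float(x) for x in r]
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(f"{path}:{ln}: ragged row ({len(vals)} values, expected {width})")
            mat.append(vals)
        w = np.array(mat)
        if w.shape[0] != w.shape[1]:
            raise ValueError(f"{path}: matrix is not square ({w.shape[0]}x{w.shape[1]})")
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(f"{path}:{rows[i][0]}: negative weight at ({i}, {j})")
        bad = np.nonzero(np.diagonal(w))[0]
        if bad.size:
            i = bad[0]
            raise ValueError(f"{path}:{rows[i][0]}: nonzero self-loop weight on node {i}")

    if directed is None:
        directed = not np.array_equal(w, w.T)
    return WeightedNetwork(w, directed=directed)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# node_index\tlabel\n")
        for i, lab in enumerate(parc.labels):
            fh.write(f"{i}\t{lab}\n")


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a two-column (node_index, label) tab/whitespace-separated table."""
    path = Path(path)
    entries: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                idx = int(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad node index {parts[0]!r}") from exc
            if idx in entries:
                raise ValueError(f"{path}:{lineno}: duplicate node index {idx}")
            entries[idx] = parts[1]
    if not entries:
        raise ValueError(f"{path}: empty parcellation file")
    if sorted(entries) != list(range(len(entries))):
        raise ValueError(f"{path}: node indices must cover 0..n-1 without gaps")
    return Parcellation([entries[i] for i in range(len(entries))])
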