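"""Binary-graph network properties.

Implements the property set used to characterize cortical-thickness
covariance networks: Watts-Strogatz clustering, characteristic path
length, Latora-Marchiori global and local efficiency, weighted global and
homologous-region connectivity, normalized betweenness centrality (NBC)
with hub detection, largest connected component, and the targeted-attack
resilience simulation.  Everything runs on plain symmetric 0/1 adjacency
matrices; heavy lifting lives in the numba kernels of :mod:`._kernels`.

Conventions (fixed here, configurable where noted):

* Characteristic path length is averaged within the largest connected
  component (``disconnected="lcc"``); a harmonic-mean alternative
  (``"harmonic"``: reciprocal of global efficiency) is available.
* Betweenness counts unordered pairs and excludes endpoints (Brandes);
  NBC divides by the network-mean betweenness so "NBC > 1.5" reads "50%
  above the average node".
* The targeted attack removes the current highest-betweenness node
  (``strategy="recalculated"``) or follows the intact graph's betweenness
  ranking (``strategy="initial"``), halting once 50% of nodes are gone;
  its scalar summary is the trapezoidal area under the relative
  largest-component-size curve over the fraction removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .atlas import RegionAtlas
from .preprocess import CorrelationMatrix

__all__ = [
    "BinaryGraph",
    "NodalScores",
    "AttackCurve",
    "clustering_index",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "global_connectivity",
    "homologous_connectivity",
    "betweenness",
    "betweenness_nbc",
    "detect_hubs",
    "largest_component",
    "targeted_attack",
    "HUB_NBC_THRESHOLD",
]

#: Hub rule: regions whose mean NBC is strictly above 1.5.
HUB_NBC_THRESHOLD = 1.5


@dataclass
class BinaryGraph:
    """Undirected unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float | None = None
    _csr: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = np.ascontiguousarray(a != 0, dtype=np.uint8)

    @classmethod
    def from_edges(cls, n: int, edges, sparsity: float | None = None) -> "BinaryGraph":
        a = np.zeros((n, n), dtype=np.uint8)
        for i, j in edges:
            a[i, j] = a[j, i] = 1
        np.fill_diagonal(a, 0)
        return cls(a, sparsity)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def csr(self):
        if self._csr is None:
            self._csr = K.csr_from_dense(self.adjacency)
        return self._csr

    def is_connected(self) -> bool:
        indptr, indices = self.csr()
        labels = K.component_labels(indptr, indices, self.n_nodes)
        return self.n_nodes <= 1 or int(labels.max()) == 0


@dataclass
class NodalScores:
    """Per-region NBC values at one sparsity."""

    values: np.ndarray
    sparsity: float | None = None


@dataclass
class AttackCurve:
    """Relative largest-component size as central nodes are removed."""

    fraction_removed: np.ndarray
    relative_lcc: np.ndarray
    strategy: str = "recalculated"

    @property
    def auc(self) -> float:
        """Trapezoidal area under the curve over the fraction removed."""
        return float(np.trapezoid(self.relative_lcc, self.fraction_removed))


def _as_graph(g) -> BinaryGraph:
    return g if isinstance(g, BinaryGraph) else BinaryGraph(g)


def clustering_index(g: BinaryGraph | np.ndarray) -> float:
    """Mean over nodes of the fraction of neighbor pairs that are linked."""
    g = _as_graph(g)
    indptr, indices = g.csr()
    return float(K.clustering_mean(indptr, indices, g.adjacency, g.n_nodes))


def _lcc_mask(g: BinaryGraph) -> np.ndarray:
    indptr, indices = g.csr()
    labels = K.component_labels(indptr, indices, g.n_nodes)
    sizes = np.bincount(labels)
    # ties: discovery order starts at the smallest node id, and argmax takes
    # the first maximum, so the LCC containing the smallest node id wins
    return labels == int(np.argmax(sizes))


def characteristic_path_length(
    g: BinaryGraph | np.ndarray, disconnected: str = "lcc"
) -> float:
    """Mean shortest-path length between node pairs.

    ``disconnected="lcc"`` (default) averages within the largest connected
    component; ``"harmonic"`` returns the reciprocal of global efficiency.
    """
    g = _as_graph(g)
    if g.n_edges == 0:
        raise ValueError("path length undefined: graph has no edges")
    indptr, indices = g.csr()
    mask = _lcc_mask(g)
    sum_d, n_pairs, sum_inv = K.distance_stats(indptr, indices, g.n_nodes, mask)
    if disconnected == "harmonic":
        n = g.n_nodes
        eff = sum_inv / (n * (n - 1))
        return float(1.0 / eff)
    if n_pairs == 0:
        raise ValueError("path length undefined: largest component is a singleton")
    return float(sum_d / n_pairs)


def global_efficiency(g: BinaryGraph | np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs; disconnected pairs contribute 0."""
    g = _as_graph(g)
    n = g.n_nodes
    if n < 2:
        return 0.0
    indptr, indices = g.csr()
    mask = np.zeros(n, dtype=bool)  # LCC stats unused here
    _, _, sum_inv = K.distance_stats(indptr, indices, n, mask)
    return float(sum_inv / (n * (n - 1)))


def local_efficiency(g: BinaryGraph | np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    g = _as_graph(g)
    indptr, indices = g.csr()
    return float(K.local_efficiency_mean(indptr, indices, g.adjacency, g.n_nodes))


def global_connectivity(corr: CorrelationMatrix | np.ndarray) -> float:
    """Mean positive correlation over all region pairs (weighted matrix).

    Computed on the correlation matrix itself, not on thresholded graphs;
    zeros from clipped negative correlations count toward the mean.
    """
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return float(r[iu, ju].mean())


def homologous_connectivity(
    corr: CorrelationMatrix | np.ndarray, atlas: RegionAtlas
) -> float:
    """Mean correlation over left-right homolog region pairs."""
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    pairs = atlas.homolog_pairs
    if len(pairs) == 0:
        raise ValueError("atlas defines no homolog pairs")
    return float(r[pairs[:, 0], pairs[:, 1]].mean())


def betweenness(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Raw Brandes betweenness (unordered pairs, endpoints excluded)."""
    g = _as_graph(g)
    indptr, indices = g.csr()
    return K.brandes_bc(indptr, indices, g.n_nodes)


def betweenness_nbc(g: BinaryGraph | np.ndarray) -> NodalScores:
    """Betweenness normalized by the network mean (NBC).

    Raises on disconnected input and when every node has zero betweenness
    (no intermediate vertices, e.g. a complete graph).
    """
    g = _as_graph(g)
    if not g.is_connected():
        raise ValueError("NBC requires a connected graph")
    bc = betweenness(g)
    mean = bc.mean()
    if mean == 0.0:
        raise ValueError("NBC undefined: no intermediate vertices")
    return NodalScores(values=bc / mean, sparsity=g.sparsity)


def detect_hubs(
    mean_nbc: np.ndarray, threshold: float = HUB_NBC_THRESHOLD
) -> np.ndarray:
    """Region ids with mean NBC strictly above the hub threshold."""
    v = np.asarray(mean_nbc, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("mean NBC must be finite")
    return np.flatnonzero(v > threshold)


def largest_component(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Node ids of the largest connected component (ties: smallest node id)."""
    g = _as_graph(g)
    return np.flatnonzero(_lcc_mask(g))


def targeted_attack(
    g: BinaryGraph | np.ndarray,
    strategy: str = "recalculated",
    horizon: float = 0.5,
) -> AttackCurve:
    """Remove the most central nodes and track the largest component.

    ``strategy="recalculated"`` recomputes betweenness after every removal
    (ties broken by lowest node id); ``"initial"`` fixes the removal order
    from the intact graph's betweenness.  Removal stops after
    ``horizon * n`` nodes.  The curve starts at the intact graph
    (fraction 0) and is normalized by the total node count.
    """
    g = _as_graph(g)
    n = g.n_nodes
    n_remove = int(np.floor(horizon * n))
    indptr, indices = g.csr()
    labels = K.component_labels(indptr, indices, n)
    lcc0 = int(np.bincount(labels).max())

    if strategy == "initial":
        bc = K.brandes_bc(indptr, indices, n)
        order = np.lexsort((np.arange(n), -bc))[:n_remove].astype(np.int64)
        sizes = K.attack_lcc_sizes(indptr, indices, n, order)
    elif strategy == "recalculated":
        active = np.ones(n, dtype=bool)
        sizes = np.empty(n_remove, dtype=np.int64)
        for step in range(n_remove):
            nodes = np.flatnonzero(active)
            sub = np.ascontiguousarray(g.adjacency[np.ix_(nodes, nodes)])
            ip, ind = K.csr_from_dense(sub)
            bc = K.brandes_bc(ip, ind, len(nodes))
            victim = nodes[np.lexsort((nodes, -bc))[0]]
            active[victim] = False
            nodes = np.flatnonzero(active)
            if len(nodes) == 0:
                sizes[step] = 0
                continue
            sub = np.ascontiguousarray(g.adjacency[np.ix_(nodes, nodes)])
            ip, ind = K.csr_from_dense(sub)
            lab = K.component_labels(ip, ind, len(nodes))
            sizes[step] = int(np.bincount(lab).max())
    else:
        raise ValueError(f"unknown attack strategy {strategy!r}")

    frac = np.arange(n_remove + 1) / n
    rel = np.concatenate([[lcc0], sizes]) / n
    return AttackCurve(fraction_removed=frac, relative_lcc=rel, strategy=strategy)
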