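"""Weighted graph metrics of coherence networks.

Four scalar properties summarize each fully weighted (no thresholding)
coherence network, in their standard Brain Connectivity Toolbox weighted
forms:

* ``CLU`` — mean Onnela weighted clustering coefficient: per node, the
  sum of cube-rooted triangle weight products, with weights normalized by
  the graph maximum, over ``k(k-1)``.
* ``LE`` — mean weighted local efficiency: per node, paths among its
  neighbors restricted to the neighborhood subgraph, combined as
  ``(w_ij * w_ih / d_jh)^{1/3}``, over ``k(k-1)``.
* ``GE`` — global efficiency: mean inverse shortest path length.
* ``L`` — characteristic path length: mean shortest path length.

Shortest paths use edge length ``1/w`` (strong coherence = short edge),
the usual convention for connection-strength weights.  With all weights
in [0, 1] this puts ``GE, CLU, LE`` in [0, 1] and ``L >= 1``, with
equality exactly on the complete unit-weight graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import CoherenceMatrix


@dataclass
class WeightedGraph:
    """Symmetric weighted graph: ``weights`` in [0, 1], zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero (no self-loops)")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = 0.5 * (w + w.T)
        np.fill_diagonal(self.weights, 0.0)
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != w.shape[0]:
                raise ValueError("label count must match node count")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class NetworkMetrics:
    """The four weighted network scalars plus the distance matrix."""

    clu: float
    le: float
    ge: float
    path_length: float
    d: np.ndarray
    edge_length: str = "inverse_weight"
    labels: tuple[str, ...] | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "clu": self.clu,
            "le": self.le,
            "ge": self.ge,
            "path_length": self.path_length,
        }


def from_coherence(cm: CoherenceMatrix) -> WeightedGraph:
    """Coherence adjacency -> graph: copy weights, zero the diagonal."""
    w = cm.values.copy()
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w, labels=cm.labels)


def _lengths(w: np.ndarray) -> np.ndarray:
    """Edge lengths 1/w; absent edges (w == 0) become +inf."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    return lengths


def shortest_paths(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest path lengths ``d_ij`` with edge length ``1/w``.

    Unreachable pairs get ``+inf``; the diagonal is 0.
    """
    lengths = _lengths(g.weights)
    # csgraph treats 0 as "no edge"; our no-edge is inf, so pass lengths
    # with inf masked to 0 and let directed=False Dijkstra do the rest.
    dense = np.where(np.isfinite(lengths), lengths, 0.0)
    d = _csgraph_shortest_path(dense, method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(g: WeightedGraph, d: np.ndarray | None = None) -> float:
    """Mean inverse shortest path length; unreachable pairs contribute 0."""
    if g.n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    if d is None:
        d = shortest_paths(g)
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum(axis=1).mean() / (g.n - 1))


def characteristic_path_length(g: WeightedGraph, d: np.ndarray | None = None) -> float:
    """Mean shortest path length over node pairs.

    Disconnected pairs are excluded from the mean with a warning; a node
    with no finite path to any other node raises.
    """
    if g.n < 2:
        raise ValueError("path length needs at least 2 nodes")
    if d is None:
        d = shortest_paths(g)
    off = ~np.eye(g.n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any(axis=1).all():
        isolated = np.where(~finite.any(axis=1))[0]
        names = (
            [g.labels[i] for i in isolated] if g.labels else isolated.tolist()
        )
        raise ValueError(f"fully disconnected node(s): {names}")
    if not finite[off].all():
        warnings.warn(
            "graph is disconnected; unreachable pairs excluded from L",
            stacklevel=2,
        )
    per_node = np.array(
        [d[i, finite[i]].mean() for i in range(g.n)]
    )
    return float(per_node.mean())


def clustering_coefficient(g: WeightedGraph) -> float:
    """Mean Onnela weighted clustering, weights normalized by the maximum.

    ``C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} / (k_i (k_i - 1))`` with
    ``w' = w / max(w)``; nodes of degree < 2 contribute 0.
    """
    if g.n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    w = g.weights
    wmax = w.max()
    if wmax == 0:
        return 0.0
    cube = np.cbrt(w / wmax)
    triangles = np.diagonal(cube @ cube @ cube)  # 2 * sum over unordered (j, h)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    ci = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return float(ci.mean())


def local_efficiency(g: WeightedGraph) -> float:
    """Mean weighted local efficiency (neighborhood-subgraph form).

    For each node ``u`` with neighbors ``V``:
    ``E_u = sum_{j != h in V} (w_uj w_uh / d_jh(V))^{1/3} / (k_u (k_u - 1))``
    where ``d_jh(V)`` is the shortest path between neighbors within the
    subgraph induced by ``V`` (node ``u`` excluded), edge length ``1/w``.
    Nodes with fewer than 2 neighbors contribute 0.
    """
    if g.n < 3:
        raise ValueError("local efficiency needs at least 3 nodes")
    w = g.weights
    eff = np.zeros(g.n)
    for u in range(g.n):
        v = np.flatnonzero(w[u] > 0)
        k = len(v)
        if k < 2:
            continue
        sub = w[np.ix_(v, v)]
        dense = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        d = _csgraph_shortest_path(dense, method="D", directed=False)
        np.fill_diagonal(d, np.inf)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d), 1.0 / d, 0.0)
        sw = np.cbrt(w[u, v])
        contrib = np.cbrt(inv_d) * np.outer(sw, sw)
        eff[u] = contrib.sum() / (k * (k - 1))
    return float(eff.mean())


def network_properties(cm: CoherenceMatrix) -> NetworkMetrics:
    """Bundle the four metrics and the distance matrix for one network."""
    g = from_coherence(cm)
    d = shortest_paths(g)
    return NetworkMetrics(
        clu=clustering_coefficient(g),
        le=local_efficiency(g),
        ge=global_efficiency(g, d),
        path_length=characteristic_path_length(g, d),
        d=d,
        labels=g.labels,
    )


__all__ = [
    "WeightedGraph",
    "NetworkMetrics",
    "from_coherence",
    "shortest_paths",
    "global_efficiency",
    "characteristic_path_length",
    "clustering_coefficient",
    "local_efficiency",
    "network_properties",
]
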