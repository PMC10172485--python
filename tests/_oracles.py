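"""Independent brute-force implementations used as test oracles.

Everything here is deliberately naive (Floyd-Warshall with explicit
triple loops, exhaustive sums over node triples, per-neighborhood
re-computation) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the classic triple loop."""
    n = lengths.shape[0]
    d = lengths.copy().astype(float)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _lengths(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    lengths = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                lengths[i, j] = 1.0 / w[i, j]
    return lengths


def global_efficiency(w: np.ndarray) -> float:
    d = floyd_warshall(_lengths(w))
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def characteristic_path_length(w: np.ndarray) -> float:
    d = floyd_warshall(_lengths(w))
    n = w.shape[0]
    per_node = []
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        per_node.append(np.mean(vals))
    return float(np.mean(per_node))


def clustering_coefficient(w: np.ndarray) -> float:
    """Onnela weighted clustering, exhaustive ordered-triple sum."""
    n = w.shape[0]
    wh = w / w.max() if w.max() > 0 else w
    cs = []
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            cs.append(0.0)
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        cs.append(s / (k * (k - 1)))
    return float(np.mean(cs))


def local_efficiency(w: np.ndarray) -> float:
    """Neighborhood-subgraph weighted efficiency, recomputed per node."""
    n = w.shape[0]
    es = []
    for u in range(n):
        nbrs = [v for v in range(n) if w[u, v] > 0]
        k = len(nbrs)
        if k < 2:
            es.append(0.0)
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(_lengths(sub))
        s = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    s += (w[u, j] * w[u, h] / d[a, b]) ** (1.0 / 3.0)
        es.append(s / (k * (k - 1)))
    return float(np.mean(es))
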