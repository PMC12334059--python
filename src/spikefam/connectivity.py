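"""Structural analysis of learned lateral weight matrices.

After learning, the weight matrix reflects how input patterns were
clustered into neuronal ensembles.  Three summary statistics capture
this structure:

* Gini index — inequality of the weight distribution over all
  off-diagonal entries (including zeros); high when a few connections
  carry most of the synaptic mass.
* transitivity — triangle density of the binarized, symmetrized graph
  (local clustering).
* betweenness centrality — how often a neuron lies on shortest paths of
  that graph; high when weakly connected neurons bridge overlapping
  ensembles.

Graph metrics operate on a binarized undirected graph: an edge (i, j)
exists iff max(w[i,j], w[j,i]) strictly exceeds a threshold, by default
the mean of the positive off-diagonal weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ConnectivityStats",
    "rescale_weights",
    "gini_index",
    "binarize",
    "transitivity",
    "betweenness_centrality",
    "pearson",
    "connectivity_stats",
]


@dataclass
class ConnectivityStats:
    gini: float
    transitivity: float
    betweenness_mean: float
    threshold_used: float


def rescale_weights(w: np.ndarray, W_total: float) -> np.ndarray:
    """Divide each neuron's incoming weights by the target row total.

    Puts matrices learned under different W_total on a common scale
    (rows of a normalized matrix then sum to 1).  Zero rows unchanged.
    """
    if W_total <= 0:
        raise ValueError("W_total must be positive")
    return w / W_total


def gini_index(w: np.ndarray) -> float:
    """Gini inequality index over all off-diagonal weights.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); 0 for equal weights,
    approaching 1 when one connection holds all the mass.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim == 2 and w.shape[0] == w.shape[1]:
        mask = ~np.eye(w.shape[0], dtype=bool)
        x = w[mask]
    else:
        x = w.ravel()
    if x.size == 0 or not (x > 0).any():
        raise ValueError("need at least one positive weight")
    x = np.sort(x)
    n = x.size
    # sorted form of the pairwise-difference definition
    cum = np.cumsum(x)
    return float((n + 1 - 2 * np.sum(cum) / cum[-1]) / n)


def binarize(w: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Symmetrized boolean adjacency: edge iff max(w[i,j], w[j,i]) > threshold.

    Default threshold is the mean of the positive off-diagonal weights
    (strict inequality: an all-equal matrix yields an empty graph).
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    if threshold is None:
        pos = w[off & (w > 0)]
        threshold = float(pos.mean()) if pos.size else 0.0
    sym = np.maximum(w, w.T)
    adj = (sym > threshold) & off
    return adj


def transitivity(adjacency: np.ndarray) -> float:
    """3 x triangles / connected triples of the undirected graph (0 if no triples)."""
    g = nx.from_numpy_array(np.asarray(adjacency, dtype=int))
    return float(nx.transitivity(g))


def betweenness_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness per node, normalized by (n-1)(n-2)/2."""
    g = nx.from_numpy_array(np.asarray(adjacency, dtype=int))
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(adjacency.shape[0])])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def connectivity_stats(
    w: np.ndarray, W_total: float, threshold: float | None = None
) -> ConnectivityStats:
    """Full structural summary of a learned (unscaled) weight matrix."""
    ws = rescale_weights(w, W_total)
    n = ws.shape[0]
    off = ~np.eye(n, dtype=bool)
    if threshold is None:
        pos = ws[off & (ws > 0)]
        threshold = float(pos.mean()) if pos.size else 0.0
    adj = binarize(ws, threshold)
    return ConnectivityStats(
        gini=gini_index(ws),
        transitivity=transitivity(adj),
        betweenness_mean=float(betweenness_centrality(adj).mean()),
        threshold_used=threshold,
    )
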