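"""Functional connectomes and their positive weighted graphs.

A functional connectome is the node-by-node matrix of Fisher-z-transformed
Pearson correlations between regional BOLD time series.  Graph metrics are
computed on the *positive* part of the connectome: negative correlations are
dropped and positive Fisher-z values become edge weights, with edge length
defined as the reciprocal weight for shortest-path computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TimeSeries",
    "Connectome",
    "WeightedGraph",
    "build_connectome",
    "to_positive_graph",
]

#: Default bound on |r| before the Fisher transform, keeping arctanh finite.
DEFAULT_R_CLIP = 0.999


@dataclass
class TimeSeries:
    """Per-subject, per-state regional BOLD time series.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    state : str
        Cognitive-state label (e.g. ``"task"`` or ``"rest"``).
    runs : sequence of ndarray
        One ``(n_nodes, n_timepoints)`` matrix per scanner run.  All runs
        must share the same node count and node order.
    node_labels : sequence of str
        Ordered node names; length must equal the node count.
    """

    subject_id: str
    state: str
    runs: Sequence[np.ndarray]
    node_labels: Sequence[str]

    def __post_init__(self) -> None:
        if len(self.runs) == 0:
            raise ValueError("TimeSeries requires at least one run")
        self.runs = [np.asarray(r, dtype=float) for r in self.runs]
        n = self.runs[0].shape[0]
        if len(self.node_labels) != n:
            raise ValueError(
                f"{len(self.node_labels)} node labels for {n} nodes"
            )
        for i, r in enumerate(self.runs):
            if r.ndim != 2 or r.shape[0] != n:
                raise ValueError(f"run {i} has node count {r.shape[0]}, expected {n}")
            if r.shape[1] < 3:
                raise ValueError(f"run {i} has {r.shape[1]} time points; need >= 3")
            sd = r.std(axis=1)
            if np.any(sd == 0):
                bad = [self.node_labels[j] for j in np.flatnonzero(sd == 0)]
                raise ValueError(
                    f"constant time series for node(s) {bad} in run {i}: "
                    "correlation undefined"
                )

    @property
    def n_nodes(self) -> int:
        return self.runs[0].shape[0]


@dataclass
class Connectome:
    """Symmetric node-by-node matrix of Fisher-z Pearson correlations."""

    subject_id: str
    state: str
    z: np.ndarray
    node_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("connectome matrix must be square")
        if len(self.node_labels) != n:
            raise ValueError("node label count does not match matrix size")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectome contains non-finite entries")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectome matrix is not symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("connectome diagonal must be exactly zero")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class WeightedGraph:
    """Nonnegative-weight undirected graph with reciprocal-weight lengths.

    ``w[i, j] == 0`` means "no edge".  ``lengths[i, j] = 1 / w[i, j]`` for
    positive weights and ``+inf`` otherwise; shortest-path distances ``d``
    over those lengths are computed lazily and cached.
    """

    w: np.ndarray
    _d: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("self-weights must be zero")
        if not np.allclose(self.w, self.w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        self.w = 0.5 * (self.w + self.w.T)  # exact symmetry

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            L = np.where(self.w > 0, 1.0 / np.where(self.w > 0, self.w, 1.0), np.inf)
        np.fill_diagonal(L, 0.0)
        return L

    @property
    def d(self) -> np.ndarray:
        """Shortest-path distance matrix (Dijkstra over edge lengths)."""
        if self._d is None:
            i, j = np.nonzero(np.triu(self.w, k=1) > 0)
            n = self.n
            data = 1.0 / self.w[i, j]
            sparse = csr_matrix(
                (np.concatenate([data, data]),
                 (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(n, n),
            )
            d = dijkstra(sparse, directed=False)
            self._d = 0.5 * (d + d.T)
        return self._d

    def degree(self) -> np.ndarray:
        """Number of neighbours of each node."""
        return (self.w > 0).sum(axis=1)


def build_connectome(ts: TimeSeries, r_clip: float = DEFAULT_R_CLIP) -> Connectome:
    """Compute a Fisher-z connectome from (possibly multi-run) time series.

    Runs are demeaned per node and concatenated along time before a single
    Pearson correlation, so multi-run sessions yield one connectome without
    inter-run mean offsets inflating correlations.  Correlations are clipped
    to ``[-r_clip, r_clip]`` to keep ``arctanh`` finite.
    """
    if not (0 < r_clip < 1):
        raise ValueError("r_clip must lie in (0, 1)")
    demeaned = [r - r.mean(axis=1, keepdims=True) for r in ts.runs]
    x = np.concatenate(demeaned, axis=1)
    r = np.corrcoef(x)
    r = np.clip(r, -r_clip, r_clip)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)
    return Connectome(ts.subject_id, ts.state, z, list(ts.node_labels))


def to_positive_graph(c: Connectome) -> WeightedGraph:
    """Reduce a connectome to its positive-weighted graph.

    Negative functional connections are excluded (most weighted graph
    measures are defined for positive weights only); an all-negative
    connectome yields an empty graph, which downstream metrics tolerate.
    """
    w = np.maximum(c.z, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)
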