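"""Weighted graph measures of integration, segregation, and centrality.

All measures operate on a :class:`~graphpm.connectome.WeightedGraph` whose
edge lengths are reciprocal weights.  Conventions:

* **Global efficiency** — mean of ``1/d_ij`` over ordered pairs ``i != j``,
  with ``1/inf := 0`` for disconnected pairs.
* **Characteristic path length** — mean shortest-path distance; when the
  graph is disconnected, the mean is taken over finite pairs only and the
  result carries a ``connected=False`` flag.
* **Clustering** — Onnela's weighted form: the geometric mean of triangle
  weights after dividing all weights by the graph maximum, so values lie in
  [0, 1]; nodes of degree < 2 score 0.
* **Local efficiency** — global efficiency of the subgraph induced on a
  node's neighbours (edge weights restricted, not rescaled).
* **Betweenness** — weighted Brandes betweenness with full shortest-path
  multiplicity counting (tied geodesics split credit), normalised by
  ``(n-1)(n-2)`` so each unordered source-target pair contributes at most
  1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import igraph as ig
import numpy as np

from .connectome import WeightedGraph

__all__ = [
    "RoiMap",
    "MetricVector",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "distance_matrix",
    "global_efficiency",
    "characteristic_path_length",
    "nodal_clustering",
    "mean_clustering",
    "nodal_local_efficiency",
    "mean_local_efficiency",
    "nodal_betweenness",
    "mean_betweenness",
    "metric_vector",
]

GLOBAL_METRICS = (
    "characteristic_path_length",
    "global_efficiency",
    "mean_clustering",
    "mean_local_efficiency",
    "mean_betweenness",
)
NODAL_METRICS = ("clustering", "local_efficiency", "betweenness")


@dataclass(frozen=True)
class RoiMap:
    """Named regions of interest mapped to 0-based node indices.

    ``entries`` maps a region name (side-tagged for bilateral regions, e.g.
    ``"L_ACC"``) to a non-empty list of node indices.  Multi-node regions
    are averaged when building metric vectors.
    """

    entries: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        for name, idx in self.entries.items():
            if len(idx) == 0:
                raise ValueError(f"ROI {name!r} has no nodes")
            if any((not float(i).is_integer()) or i < 0 for i in idx):
                raise ValueError(f"ROI {name!r} has invalid node indices {list(idx)}")

    def validate(self, n: int) -> None:
        for name, idx in self.entries.items():
            if any(i >= n for i in idx):
                raise ValueError(
                    f"ROI {name!r} references node >= {n} (graph has {n} nodes)"
                )

    @property
    def names(self) -> list[str]:
        return list(self.entries.keys())


@dataclass
class MetricVector:
    """Named graph-metric features for one subject and state.

    ``values`` holds the five global measures plus, for each ROI,
    ``"<roi>:clustering"``, ``"<roi>:local_efficiency"`` and
    ``"<roi>:betweenness"``.  A value may be NaN (with ``connected=False``)
    when the measure is undefined, e.g. path length of an empty graph.
    """

    subject_id: str
    state: str
    values: dict[str, float]
    connected: bool = True


class PathLength(NamedTuple):
    value: float
    connected: bool


def distance_matrix(g: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path distances over reciprocal-weight lengths."""
    return g.d


def global_efficiency(g: WeightedGraph, d: np.ndarray | None = None) -> float:
    """Average inverse shortest-path length over ordered node pairs."""
    if g.n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = g.d if d is None else d
    return _efficiency_from_distances(d)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(g: WeightedGraph, d: np.ndarray | None = None) -> PathLength:
    """Mean shortest-path distance over node pairs.

    Disconnected pairs are excluded from the mean and flagged via
    ``connected=False``; a graph with no finite pair at all raises.
    """
    d = g.d if d is None else d
    mask = np.isfinite(d)
    np.fill_diagonal(mask, False)
    if not mask.any():
        raise ValueError("characteristic path length undefined: no connected pair")
    connected = bool(mask.sum() == g.n * (g.n - 1))
    return PathLength(float(d[mask].mean()), connected)


def nodal_clustering(g: WeightedGraph) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With weights normalised by the graph maximum,
    ``C_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1))``; nodes with
    fewer than two neighbours score 0.
    """
    wmax = g.w.max()
    if wmax == 0:
        return np.zeros(g.n)
    cbrt = np.cbrt(g.w / wmax)
    triangles = np.diag(cbrt @ cbrt @ cbrt)  # 2x number of weighted triangles at i
    k = g.degree()
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c


def mean_clustering(g: WeightedGraph) -> float:
    return float(nodal_clustering(g).mean())


def nodal_local_efficiency(g: WeightedGraph) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph.

    Edges of the subgraph keep their original weights; nodes with fewer
    than two neighbours score 0.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra as _dijkstra

    out = np.zeros(g.n)
    for i in range(g.n):
        nbr = np.flatnonzero(g.w[i] > 0)
        if nbr.size < 2:
            continue
        sw = g.w[np.ix_(nbr, nbr)]
        ii, jj = np.nonzero(sw > 0)
        lengths = csr_matrix((1.0 / sw[ii, jj], (ii, jj)), shape=sw.shape)
        d = _dijkstra(lengths, directed=False)
        out[i] = _efficiency_from_distances(d)
    return out


def mean_local_efficiency(g: WeightedGraph) -> float:
    return float(nodal_local_efficiency(g).mean())


def nodal_betweenness(g: WeightedGraph) -> np.ndarray:
    """Weighted betweenness centrality normalised by ``(n-1)(n-2)``.

    Shortest paths are taken over reciprocal-weight lengths; tied geodesics
    split credit equally (Brandes multiplicity counting).  Graphs with
    fewer than 3 nodes score 0 everywhere.
    """
    n = g.n
    if n < 3:
        return np.zeros(n)
    i, j = np.nonzero(np.triu(g.w, k=1) > 0)
    graph = ig.Graph(n, list(zip(i.tolist(), j.tolist())))
    if len(i) == 0:
        return np.zeros(n)
    raw = graph.betweenness(weights=(1.0 / g.w[i, j]).tolist())
    return np.asarray(raw) / ((n - 1) * (n - 2))


def mean_betweenness(g: WeightedGraph) -> float:
    return float(nodal_betweenness(g).mean())


def metric_vector(
    g: WeightedGraph,
    roi: RoiMap | None = None,
    subject_id: str = "",
    state: str = "",
) -> MetricVector:
    """Five global measures plus three nodal measures per ROI.

    Multi-node ROIs are averaged (arithmetic mean across their nodes).  An
    empty graph records NaN path length with the connectedness flag unset.
    """
    if roi is not None:
        roi.validate(g.n)
    d = g.d
    clu = nodal_clustering(g)
    loc = nodal_local_efficiency(g)
    btw = nodal_betweenness(g)
    values: dict[str, float] = {}
    try:
        cpl = characteristic_path_length(g, d)
        values["characteristic_path_length"] = cpl.value
        connected = cpl.connected
    except ValueError:
        values["characteristic_path_length"] = float("nan")
        connected = False
    values["global_efficiency"] = global_efficiency(g, d)
    values["mean_clustering"] = float(clu.mean())
    values["mean_local_efficiency"] = float(loc.mean())
    values["mean_betweenness"] = float(btw.mean())
    if roi is not None:
        for name, idx in roi.entries.items():
            idx = list(idx)
            values[f"{name}:clustering"] = float(clu[idx].mean())
            values[f"{name}:local_efficiency"] = float(loc[idx].mean())
            values[f"{name}:betweenness"] = float(btw[idx].mean())
    return MetricVector(subject_id, state, values, connected)
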