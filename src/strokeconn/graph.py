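"""Binary graph construction and nodal graph-theory metrics.

A subject's ROI-to-ROI correlation matrix is binarized over a sweep of
thresholds tau (default 0.15-0.50 in steps of 0.01); at each tau the
supra-threshold correlations define an undirected, unweighted graph on the
ROIs.  Three nodal metrics are computed at every threshold:

* global efficiency (GE): mean inverse shortest-path length from the node
  to every other node, with 1/inf = 0 for unreachable nodes;
* clustering coefficient (CC): fraction of the possible edges among the
  node's neighbours that are present (0 when degree < 2);
* betweenness centrality (BC): fraction of shortest paths between other
  node pairs that pass through the node, with fractional counting of tied
  shortest paths, normalized by (n-1)(n-2)/2 so it lies in [0, 1].

Each metric-versus-threshold curve is then collapsed to a single scalar
per node by trapezoidal area under the curve (AUC), giving a summary that
does not depend on any single threshold choice.

All metrics are implemented directly (BFS for path lengths, Brandes'
accumulation for betweenness); no graph library is used.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

METRICS = ("GE", "CC", "BC")

DEFAULT_TAU_GRID = np.round(np.arange(0.15, 0.50 + 1e-9, 0.01), 10)


@dataclass
class AdjacencyGraph:
    """Undirected binary graph at a single threshold."""

    A: np.ndarray  # symmetric {0,1}, zero diagonal
    tau: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency matrix must have a zero diagonal")
        self.A = A.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@dataclass
class ThresholdSweepResult:
    """Nodal metric values over the threshold grid.

    ``values[metric]`` is an (n_thresholds, n_nodes) array.
    """

    thresholds: np.ndarray
    values: dict[str, np.ndarray]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("threshold grid must be strictly increasing with >= 2 points")
        self.thresholds = t


@dataclass
class GraphMetricAUC:
    """Per node x metric AUC over the threshold grid."""

    auc: dict[str, np.ndarray]  # metric -> (n_nodes,)
    tau_min: float
    tau_max: float
    labels: list[str] | None = None


def binarize(weights: np.ndarray, tau: float, labels: list[str] | None = None) -> AdjacencyGraph:
    """Binary adjacency: edge present iff weight strictly exceeds ``tau``.

    The diagonal is ignored; negative weights never create edges for any
    tau >= 0.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, equal_nan=True):
        raise ValueError("weight matrix must be symmetric")
    with np.errstate(invalid="ignore"):
        A = (W > tau).astype(np.int8)
    np.fill_diagonal(A, 0)
    A = np.maximum(A, A.T)
    return AdjacencyGraph(A=A, tau=float(tau), labels=labels)


def shortest_path_lengths(A: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by BFS; ``inf`` for unreachable pairs."""
    A = np.asarray(A)
    n = A.shape[0]
    neighbors = [np.flatnonzero(A[i]) for i in range(n)]
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0.0
        q = deque([s])
        while q:
            v = q.popleft()
            dv = D[s, v]
            for w in neighbors[v]:
                if np.isinf(D[s, w]):
                    D[s, w] = dv + 1.0
                    q.append(w)
    return D


def global_efficiency_nodes(A: np.ndarray) -> np.ndarray:
    """Nodal global efficiency: mean of 1/d(i, j) over j != i (1/inf = 0)."""
    A = np.asarray(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D = shortest_path_lengths(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency_node(A: np.ndarray, node: int) -> float:
    return float(global_efficiency_nodes(A)[node])


def clustering_coefficient_nodes(A: np.ndarray) -> np.ndarray:
    """Nodal clustering coefficient: present / possible edges among neighbours."""
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1)
    # A^3 diagonal counts closed triangles through each node (x2 per triangle)
    tri = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, tri / denom, 0.0)
    return cc


def clustering_coefficient_node(A: np.ndarray, node: int) -> float:
    return float(clustering_coefficient_nodes(A)[node])


def betweenness_centrality_nodes(A: np.ndarray) -> np.ndarray:
    """Nodal betweenness via Brandes' algorithm, normalized to [0, 1].

    Tied shortest paths are counted fractionally; pairs in different
    components contribute nothing.  The raw unordered-pair sum is divided
    by (n-1)(n-2)/2.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if n < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    neighbors = [np.flatnonzero(A[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path counts
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        order: list[int] = []
        q = deque([s])
        preds: list[list[int]] = [[] for _ in range(n)]
        while q:
            v = q.popleft()
            order.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # ordered-pair sum -> unordered pairs, then normalize
    bc /= 2.0
    bc /= (n - 1) * (n - 2) / 2.0
    return bc


def betweenness_centrality_node(A: np.ndarray, node: int) -> float:
    return float(betweenness_centrality_nodes(A)[node])


_METRIC_FN = {
    "GE": global_efficiency_nodes,
    "CC": clustering_coefficient_nodes,
    "BC": betweenness_centrality_nodes,
}


def metric_threshold_sweep(
    weights: np.ndarray,
    grid: np.ndarray | None = None,
    labels: list[str] | None = None,
    metrics: tuple[str, ...] = METRICS,
) -> ThresholdSweepResult:
    """Compute GE/CC/BC for every node at every threshold of ``grid``."""
    grid = DEFAULT_TAU_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.abs(grid) >= 1):
        raise ValueError("thresholds must lie in (-1, 1) for correlation weights")
    n = np.asarray(weights).shape[0]
    values = {m: np.empty((grid.size, n)) for m in metrics}
    for t_idx, tau in enumerate(grid):
        A = binarize(weights, tau).A
        for m in metrics:
            values[m][t_idx] = _METRIC_FN[m](A)
    return ThresholdSweepResult(thresholds=grid, values=values, labels=labels)


def auc(sweep: ThresholdSweepResult) -> GraphMetricAUC:
    """Trapezoidal area under each node's metric-versus-threshold curve."""
    out = {
        m: np.trapezoid(vals, sweep.thresholds, axis=0)
        for m, vals in sweep.values.items()
    }
    return GraphMetricAUC(
        auc=out,
        tau_min=float(sweep.thresholds[0]),
        tau_max=float(sweep.thresholds[-1]),
        labels=sweep.labels,
    )


def graph_metric_aucs(
    weights: np.ndarray,
    grid: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> GraphMetricAUC:
    """Convenience: threshold sweep followed by AUC summarization."""
    return auc(metric_threshold_sweep(weights, grid=grid, labels=labels))
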