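"""Correlation clustering (maximizing agreements) on signed similarity graphs.

Well-formedness of a color partition is the correlation-clustering objective:
on a complete graph over the chips with edge weight ``sim(u, v) - 1/2``, the
score of a clustering is the total weight of intra-cluster edges, and the
optimal clustering maximizes it.  The problem is NP-hard; :func:`solve` is a
greedy best-move local search with seeded restarts (local optimality only),
and :func:`brute_force` enumerates all set partitions for small instances as
an exact oracle.  :func:`consensus` aggregates many partitions of the same
chart into one by clustering co-assignment judgments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .color_domain import ChipChart, SimilarityParams, similarity_matrix
from .partitioning import Partition

__all__ = [
    "WeightedGraph",
    "build_similarity_graph",
    "build_consensus_graph",
    "objective",
    "solve",
    "brute_force",
    "consensus",
]

BRUTE_FORCE_MAX = 12


@dataclass(frozen=True)
class WeightedGraph:
    """Complete graph with a symmetric signed weight matrix and zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def build_similarity_graph(
    chart: ChipChart, simp: SimilarityParams = SimilarityParams()
) -> WeightedGraph:
    """Graph on the chips with edge weight ``sim(u, v) - 1/2``."""
    return WeightedGraph(similarity_matrix(chart, simp) - 0.5)


def build_consensus_graph(partitions: Sequence[Partition]) -> WeightedGraph:
    """Graph whose weight is the co-assignment frequency minus 1/2.

    Each partition casts a similarity judgment (+) for pairs it puts in the
    same category and a dissimilarity judgment (-) otherwise; the weight is
    the fraction of similarity judgments minus the majority threshold 1/2.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    charts = {p.chart_ref for p in partitions}
    if len(charts) > 1:
        raise ValueError(f"partitions come from different charts: {sorted(charts)}")
    sizes = {p.n_chips for p in partitions}
    if len(sizes) > 1:
        raise ValueError("partitions have inconsistent sizes")
    n = partitions[0].n_chips
    co = np.zeros((n, n))
    for p in partitions:
        lab = p.label_array()
        co += lab[:, None] == lab[None, :]
    return WeightedGraph(co / len(partitions) - 0.5)


def objective(graph: WeightedGraph, labels: np.ndarray) -> float:
    """Total weight on intra-cluster edges (each unordered pair once)."""
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(np.sum(graph.weights * same) / 2.0)


def _local_search(
    w: np.ndarray, labels: np.ndarray, max_clusters: int | None
) -> np.ndarray:
    """Greedy best-move local search.

    Sweeps nodes in chip-id order, moving each to the cluster (possibly a
    fresh singleton) that most increases the objective; every accepted move
    strictly improves it, so the objective is monotone non-decreasing and the
    search terminates at a local optimum.  Ties prefer the lowest-indexed
    existing cluster; opening a new cluster is forbidden when it would exceed
    ``max_clusters``.
    """
    n = w.shape[0]
    _, labels = np.unique(labels, return_inverse=True)
    k = int(labels.max()) + 1
    member = np.zeros((n, k))
    member[np.arange(n), labels] = 1.0
    attach = w @ member  # attach[u, c] = total weight from u into cluster c
    sizes = member.sum(axis=0).astype(int)

    improved = True
    while improved:
        improved = False
        for u in range(n):
            cu = labels[u]
            gains = attach[u] - attach[u, cu]
            gains[sizes == 0] = -np.inf  # empty slots count as opening a cluster
            gains[cu] = 0.0
            gain = gains.max()
            c = int(np.flatnonzero(gains == gain)[0])  # lowest index wins ties
            n_used = int(np.sum(sizes > 0))
            can_open = (max_clusters is None or n_used < max_clusters) and sizes[cu] > 1
            if can_open and -attach[u, cu] > gain + 1e-12:
                gain, c = -attach[u, cu], -1  # relocate to a fresh singleton
            if gain > 1e-12 and c != cu:
                if c < 0:
                    empty = np.flatnonzero(sizes == 0)
                    if empty.size:
                        c = int(empty[0])
                    else:
                        attach = np.hstack([attach, np.zeros((n, 1))])
                        sizes = np.append(sizes, 0)
                        c = k
                        k += 1
                attach[:, cu] -= w[:, u]
                attach[:, c] += w[:, u]
                sizes[cu] -= 1
                sizes[c] += 1
                labels[u] = c
                improved = True
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def solve(
    graph: WeightedGraph,
    restarts: int = 20,
    rng: np.random.Generator | None = None,
    max_clusters: int | None = None,
    chart_ref: str = "chart",
) -> tuple[Partition, float]:
    """Best local-search clustering over seeded restarts.

    Restart 0 starts from all-singletons (capped at ``max_clusters`` by random
    grouping when given); later restarts start from random assignments into
    ``min(n, max_clusters or n)`` groups.  Returns the partition and its
    objective value.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = graph.n
    cap = n if max_clusters is None else min(max_clusters, n)
    if cap < 1:
        raise ValueError("max_clusters must be >= 1")

    best_labels, best_obj = None, -np.inf
    for r in range(restarts):
        if r == 0:
            start = np.arange(n) % cap
        else:
            start = rng.integers(0, cap, size=n)
        labels = _local_search(graph.weights, start, max_clusters)
        obj = objective(graph, labels)
        if obj > best_obj + 1e-12:
            best_labels, best_obj = labels, obj
    return Partition.from_array(best_labels, chart_ref=chart_ref), best_obj


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(0, 0)


def brute_force(graph: WeightedGraph, chart_ref: str = "chart") -> tuple[Partition, float]:
    """Exact optimum by exhausting all set partitions; refuses n > 12."""
    if graph.n > BRUTE_FORCE_MAX:
        raise ValueError(f"brute force limited to n <= {BRUTE_FORCE_MAX}, got {graph.n}")
    best_labels, best_obj = None, -np.inf
    for labels in _set_partitions(graph.n):
        obj = objective(graph, labels)
        if obj > best_obj:
            best_labels, best_obj = labels, obj
    return Partition.from_array(best_labels, chart_ref=chart_ref), best_obj


def consensus(
    partitions: Sequence[Partition],
    restarts: int = 20,
    rng: np.random.Generator | None = None,
    max_clusters: int | None = None,
) -> Partition:
    """Aggregate partitions of one chart into a single consensus partition.

    Builds the co-assignment graph and solves correlation clustering on it.
    When every weight is <= 0 (no pair co-assigned by a majority) the solver's
    deterministic start returns all-singletons, the documented tie policy.
    """
    graph = build_consensus_graph(partitions)
    part, _ = solve(
        graph, restarts=restarts, rng=rng, max_clusters=max_clusters,
        chart_ref=partitions[0].chart_ref,
    )
    return part
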