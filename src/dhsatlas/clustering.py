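"""Cross-sample peak alignment by Markov clustering of interval-overlap graphs.

Each peak is a graph node; two peaks on the same chromosome that overlap are
joined by an edge weighted with the Jaccard similarity of their intervals
(intersection length / union length, in bp, half-open arithmetic). The graph
is built per chromosome with a sweep over start-sorted peaks, decomposed
into connected components, and each non-trivial component is partitioned by
Markov clustering (MCL): alternate expansion (matrix power) and inflation
(entrywise power with column renormalisation), pruning small entries, until
the iteration stabilises; clusters are read off as attractor systems.

The resulting DHS clusters partition the input peak set: every peak belongs
to exactly one cluster, and the cluster span runs from the minimum member
start to the maximum member end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .exceptions import ConfigError
from .io import GenomicInterval, Peak, chrom_sort_key

# components smaller than this are clustered with dense arithmetic
_DENSE_LIMIT = 400


@dataclass(frozen=True)
class MCLParams:
    """MCL tuning knobs, pinned to the algorithm's classical defaults."""

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iterations: int = 100
    self_loop_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ConfigError("inflation must be > 1")
        if int(self.expansion) != self.expansion or self.expansion < 2:
            raise ConfigError("expansion must be an integer >= 2")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise ConfigError("tolerances must be > 0")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.self_loop_weight <= 0:
            raise ConfigError("self_loop_weight must be > 0")


@dataclass
class PeakGraph:
    """Interval-overlap graph over the peaks of one chromosome.

    Nodes are indices into ``peaks`` (held in a canonical sorted order so
    the downstream partition is independent of input order). Edges are
    parallel arrays; weights are Jaccard similarities in (0, 1].
    """

    peaks: list[Peak]
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_weight: np.ndarray
    self_loop_weight: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.peaks)

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_nodes
        ij = np.concatenate([self.edge_i, self.edge_j])
        ji = np.concatenate([self.edge_j, self.edge_i])
        w = np.concatenate([self.edge_weight, self.edge_weight])
        return sp.csr_matrix((w, (ij, ji)), shape=(n, n))


@dataclass(frozen=True)
class DHSCluster:
    """A cross-sample aligned regulatory site."""

    cluster_id: str
    members: tuple[Peak, ...]
    span: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(p.sample_id for p in self.members)

    def peaks_of_sample(self, sample_id: str) -> list[Peak]:
        return [p for p in self.members if p.sample_id == sample_id]


def interval_similarity(a: GenomicInterval, b: GenomicInterval) -> float:
    """Jaccard similarity of two intervals: |a∩b| / |a∪b| in bp.

    Zero for different chromosomes or disjoint intervals; 1 for identical
    intervals; symmetric.
    """
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    union = len(a) + len(b) - inter
    return inter / union


def _peak_sort_key(p: Peak):
    return (p.interval.start, p.interval.end, p.sample_id, p.neglog10_p, p.signal)


def build_graph(peaks: Sequence[Peak], self_loop_weight: float = 1.0) -> PeakGraph:
    """Build the overlap graph for the peaks of one chromosome.

    Uses a start-sorted sweep with an active window, so only overlapping
    pairs are ever visited (never all pairs over the chromosome).
    """
    chroms = {p.interval.chrom for p in peaks}
    if len(chroms) > 1:
        raise ValueError(f"peaks span multiple chromosomes: {sorted(chroms)}")
    ordered = sorted(peaks, key=_peak_sort_key)
    ei: list[int] = []
    ej: list[int] = []
    ew: list[float] = []
    active: list[int] = []  # indices with interval possibly still open
    for k, pk in enumerate(ordered):
        start_k = pk.interval.start
        if active:
            active = [j for j in active if ordered[j].interval.end > start_k]
        for j in active:
            w = interval_similarity(ordered[j].interval, pk.interval)
            if w > 0:
                ei.append(j)
                ej.append(k)
                ew.append(w)
        active.append(k)
    return PeakGraph(
        peaks=ordered,
        edge_i=np.asarray(ei, dtype=np.int64),
        edge_j=np.asarray(ej, dtype=np.int64),
        edge_weight=np.asarray(ew, dtype=np.float64),
        self_loop_weight=self_loop_weight,
    )


def graph_components(graph: PeakGraph) -> list[np.ndarray]:
    """Maximal connected components, each an array of node indices.

    Components are ordered by their smallest member index; singletons pass
    through (the caller can skip MCL for them).
    """
    if graph.n_nodes == 0:
        return []
    n_comp, labels = _cc(graph.adjacency(), directed=False)
    order = np.argsort(labels, kind="stable")
    comps: list[np.ndarray] = []
    bounds = np.flatnonzero(np.diff(labels[order])) + 1
    for chunk in np.split(order, bounds):
        comps.append(np.sort(chunk))
    comps.sort(key=lambda c: c[0])
    return comps


def _column_normalize_dense(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=0)
    s[s == 0] = 1.0
    return M / s


def _mcl_dense(M: np.ndarray, params: MCLParams) -> tuple[np.ndarray, bool]:
    M = _column_normalize_dense(M.astype(np.float64, copy=True))
    for _ in range(params.max_iterations):
        prev = M
        M = np.linalg.matrix_power(prev, params.expansion)
        np.power(M, params.inflation, out=M)
        M[M < params.prune_threshold] = 0.0
        M = _column_normalize_dense(M)
        if np.abs(M - prev).max() < params.convergence_tol:
            return M, True
    return M, False


def _mcl_sparse(M: sp.csr_matrix, params: MCLParams) -> tuple[np.ndarray, bool]:
    M = sp.csc_matrix(M, dtype=np.float64)
    inv = 1.0 / np.asarray(M.sum(axis=0)).ravel()
    M = M @ sp.diags(inv)
    for _ in range(params.max_iterations):
        prev = M
        for _ in range(params.expansion - 1):
            M = M @ prev
        M = M.power(params.inflation)
        M.data[M.data < params.prune_threshold] = 0.0
        M.eliminate_zeros()
        s = np.asarray(M.sum(axis=0)).ravel()
        s[s == 0] = 1.0
        M = M @ sp.diags(1.0 / s)
        delta = abs(M - prev)
        change = delta.data.max() if delta.nnz else 0.0
        if change < params.convergence_tol:
            return np.asarray(M.todense()), True
    return np.asarray(M.todense()), False


def mcl_partition(
    adjacency: np.ndarray | sp.spmatrix,
    params: MCLParams = MCLParams(),
    *,
    add_self_loops: bool = True,
) -> tuple[list[list[int]], bool]:
    """Partition a weighted graph with MCL.

    Returns (clusters, converged). Clusters are read off the limit matrix as
    attractor systems: attractor nodes (positive diagonal) that attract each
    other form one system, and every node is assigned to the system with the
    largest total attraction weight (ties to the lowest-index system).
    Non-convergence at ``max_iterations`` emits a warning and returns the
    partition of the current iterate.
    """
    if sp.issparse(adjacency):
        A = adjacency.tocsr().astype(np.float64)
    else:
        A = np.asarray(adjacency, dtype=np.float64)
    n = A.shape[0]
    if n == 0:
        return [], True
    if add_self_loops:
        if sp.issparse(A):
            A = A + params.self_loop_weight * sp.eye(n, format="csr")
        else:
            A = A + params.self_loop_weight * np.eye(n)
    if n <= _DENSE_LIMIT:
        M, converged = _mcl_dense(A.toarray() if sp.issparse(A) else A, params)
    else:
        M, converged = _mcl_sparse(sp.csr_matrix(A), params)
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations "
            f"on a component of {n} nodes; returning current partition",
            RuntimeWarning,
            stacklevel=2,
        )
    return _read_attractor_systems(M), converged


def _read_attractor_systems(M: np.ndarray) -> list[list[int]]:
    n = M.shape[0]
    attractors = np.flatnonzero(np.diag(M) > 0)
    if attractors.size == 0:
        # pathological (should not occur with self-loops); everyone separate
        return [[i] for i in range(n)]
    # union attractors that attract each other into systems
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aset = set(int(a) for a in attractors)
    for a in attractors:
        for b in np.flatnonzero(M[a] > 0):
            if int(b) in aset:
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(int(a)) for a in attractors})
    system_index = {r: k for k, r in enumerate(roots)}
    systems: dict[int, list[int]] = {k: [] for k in range(len(roots))}
    rows_of_system: dict[int, list[int]] = {k: [] for k in range(len(roots))}
    for a in attractors:
        rows_of_system[system_index[find(int(a))]].append(int(a))
    # attraction weight of node j to a system = summed mass from its rows
    W = np.zeros((len(roots), n))
    for k, rows in rows_of_system.items():
        W[k] = M[rows].sum(axis=0)
    best = np.argmax(W, axis=0)  # argmax takes the smallest index on ties
    unattracted = set(np.flatnonzero(W.max(axis=0) <= 0).tolist())
    clusters: dict[int, list[int]] = {}
    for j in range(n):
        if j in unattracted:
            clusters.setdefault(len(roots) + j, []).append(j)
        else:
            clusters.setdefault(int(best[j]), []).append(j)
    return [sorted(members) for _, members in sorted(clusters.items())]


def cluster_component(
    graph: PeakGraph, component: np.ndarray, params: MCLParams
) -> list[list[int]]:
    """Run MCL on one connected component; returns node-index clusters."""
    if component.size == 1:
        return [[int(component[0])]]
    A = graph.adjacency()[component][:, component]
    clusters, _ = mcl_partition(A, params)
    return [[int(component[i]) for i in cl] for cl in clusters]


def cluster_all(
    peaks: Iterable[Peak], params: MCLParams = MCLParams()
) -> list[DHSCluster]:
    """Cluster peaks across samples into DHS clusters, genome-wide.

    Builds a per-chromosome overlap graph, extracts connected components,
    and runs MCL per non-singleton component. The result partitions the
    input peaks and is deterministic given inputs and parameters.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    if not by_chrom:
        warnings.warn("no input peaks; returning empty cluster set", RuntimeWarning)
        return []
    raw: list[tuple[GenomicInterval, tuple[Peak, ...]]] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        graph = build_graph(by_chrom[chrom], params.self_loop_weight)
        for comp in graph_components(graph):
            for node_ids in cluster_component(graph, comp, params):
                members = tuple(graph.peaks[i] for i in node_ids)
                span = GenomicInterval(
                    chrom,
                    min(p.interval.start for p in members),
                    max(p.interval.end for p in members),
                )
                raw.append((span, members))
    raw.sort(key=lambda item: (chrom_sort_key(item[0].chrom), item[0].start, item[0].end))
    width = max(7, len(str(len(raw))))
    return [
        DHSCluster(cluster_id=f"DHS{k:0{width}d}", members=members, span=span)
        for k, (span, members) in enumerate(raw, start=1)
    ]


# ---------------------------------------------------------------------------
# Tabular (de)serialisation of clusters


def clusters_to_frame(clusters: Sequence[DHSCluster]) -> pd.DataFrame:
    """Flatten clusters to a membership table (one row per member peak)."""
    rows = []
    for c in clusters:
        for p in c.members:
            rows.append(
                (
                    c.cluster_id,
                    c.span.chrom,
                    c.span.start,
                    c.span.end,
                    p.interval.start,
                    p.interval.end,
                    p.sample_id,
                    p.neglog10_p,
                    p.signal,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "chrom",
            "span_start",
            "span_end",
            "peak_start",
            "peak_end",
            "sample_id",
            "neglog10_p",
            "signal",
        ],
    )


def clusters_from_frame(df: pd.DataFrame) -> list[DHSCluster]:
    """Rebuild :class:`DHSCluster` objects from a membership table."""
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        chrom = grp["chrom"].iloc[0]
        members = tuple(
            Peak(
                GenomicInterval(chrom, int(r.peak_start), int(r.peak_end)),
                r.sample_id,
                float(r.neglog10_p),
                float(r.signal),
            )
            for r in grp.itertuples()
        )
        span = GenomicInterval(
            chrom, int(grp["span_start"].iloc[0]), int(grp["span_end"].iloc[0])
        )
        clusters.append(DHSCluster(str(cid), members, span))
    clusters.sort(key=lambda c: (chrom_sort_key(c.chrom), c.span.start, c.span.end))
    return clusters


def cluster_spans(clusters: Sequence[DHSCluster]) -> pd.DataFrame:
    """Span table indexed by cluster_id (chrom, start, end, n_members)."""
    return pd.DataFrame(
        {
            "chrom": [c.span.chrom for c in clusters],
            "start": [c.span.start for c in clusters],
            "end": [c.span.end for c in clusters],
            "n_members": [len(c.members) for c in clusters],
        },
        index=pd.Index([c.cluster_id for c in clusters], name="cluster_id"),
    )
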