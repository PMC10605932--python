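"""Sparsity thresholding and graph-theoretical metrics for similarity networks.

A similarity matrix is binarized at a *sparsity* s by keeping the
``floor(s * N(N-1)/2)`` largest off-diagonal entries as undirected, unweighted
edges (ties at the cutoff broken by ascending (i, j) order, so the result is
deterministic). The analysis sweep runs s = 0.10 .. 0.60 in steps of 0.02 (26
levels); the lower bound guards against network fragmentation and the upper
bound against increasingly random, non-biological topology. Because every
level keeps a prefix of the same similarity ranking, sweep graphs are nested.

Global metrics: clustering coefficient Cp, characteristic path length Lp
(averaged over connected pairs only), global efficiency Eglob (mean inverse
shortest-path length over ordered pairs, 1/inf = 0) and local efficiency Eloc
(mean over nodes of the global efficiency of the neighbor-induced subgraph).
Small-world indices gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null> and
sigma = gamma/lambda are computed against degree-preserving double-edge-swap
null networks. Nodal betweenness centrality is left unnormalized (each
unordered pair counted once). Per-metric curves over the sweep are summarised
by the trapezoidal area under the curve (AUC) in sparsity units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import igraph as ig
import numpy as np

__all__ = [
    "SPARSITY_GRID",
    "ThresholdedGraph",
    "MetricCurve",
    "threshold_at_sparsity",
    "sparsity_sweep",
    "compute_global_metrics",
    "betweenness_centrality",
    "rewire_null",
    "small_world_indices",
    "auc_over_sparsity",
    "analyze_subject",
    "GLOBAL_METRICS",
]

#: the standard 26-level sparsity grid, 10%..60% step 2%
SPARSITY_GRID = np.round(np.arange(0.10, 0.6001, 0.02), 10)

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma")


@dataclass(frozen=True)
class ThresholdedGraph:
    """Binary undirected graph at one sparsity level (no self-loops)."""

    n_nodes: int
    sparsity: float
    edges: np.ndarray  # (K, 2) int array, i < j

    @cached_property
    def graph(self) -> ig.Graph:
        return ig.Graph(n=self.n_nodes, edges=self.edges.tolist())

    @cached_property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if self.edges.size:
            a[self.edges[:, 0], self.edges[:, 1]] = True
        return a | a.T

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def is_fragmented(self) -> bool:
        return len(self.graph.connected_components()) > 1


def _ranked_pairs(matrix: np.ndarray):
    """Upper-triangle pairs ordered by descending similarity, ties by (i, j)."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.ndim != 2 or matrix.shape[1] != n:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=0, rtol=0):
        raise ValueError("similarity matrix must be symmetric")
    ii, jj = np.triu_indices(n, 1)
    vals = matrix[ii, jj]
    # lexsort: last key is primary
    order = np.lexsort((jj, ii, -vals))
    return n, np.column_stack((ii[order], jj[order]))


def threshold_at_sparsity(matrix: np.ndarray, sparsity: float) -> ThresholdedGraph:
    """Keep the ``floor(s * N(N-1)/2)`` strongest edges of a similarity matrix."""
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    n, ranked = _ranked_pairs(matrix)
    k = int(np.floor(sparsity * n * (n - 1) / 2))
    return ThresholdedGraph(n, float(sparsity), ranked[:k])


def sparsity_sweep(matrix: np.ndarray, grid=None) -> list[ThresholdedGraph]:
    """Threshold at every sparsity in the grid (default 0.10..0.60 step 0.02).

    The similarity ranking is computed once and each level keeps a prefix of
    it, so the returned graphs are nested by construction.
    """
    if grid is None:
        grid = SPARSITY_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("sparsity grid must lie in (0, 1]")
    n, ranked = _ranked_pairs(matrix)
    out = []
    for s in grid:
        k = int(np.floor(s * n * (n - 1) / 2))
        out.append(ThresholdedGraph(n, float(s), ranked[:k]))
    return out


def _closure_metrics(adj: np.ndarray, need_cp: bool, need_paths: bool) -> dict:
    """Cp, Lp and Eglob from dense boolean adjacency.

    Distances come from an iterated boolean-reachability closure (one matrix
    product per additional path length), exact for binary graphs: Lp averages
    over connected pairs only (NaN when there are none), Eglob averages 1/d
    over all ordered pairs with 1/inf = 0, Cp is the mean per-node
    transitivity with 0 for degree < 2.
    """
    n = adj.shape[0]
    A = adj.astype(np.float32)
    out = {}
    if need_cp:
        deg = adj.sum(axis=1)
        # (A^2 * A) row sums count closed 2-paths through each node, twice
        tri = ((A @ A) * A).sum(axis=1).astype(np.float64) / 2.0
        pairs = deg * (deg - 1) / 2.0
        out["Cp"] = float(np.where(deg >= 2,
                                   tri / np.maximum(pairs, 1.0), 0.0).mean())
    if need_paths:
        reach = A + np.eye(n, dtype=np.float32)
        count = int(adj.sum())  # ordered pairs at distance 1
        total_d = float(count)
        total_inv = float(count)
        n_connected = count
        d = 1
        while True:
            nxt = (reach @ A) > 0
            new = nxt & (reach == 0)
            count = int(new.sum())
            if count == 0:
                break
            d += 1
            total_d += d * count
            total_inv += count / d
            n_connected += count
            reach[new] = 1.0
        out["Lp"] = total_d / n_connected if n_connected else float("nan")
        out["Eglob"] = total_inv / (n * (n - 1)) if n > 1 else 0.0
    return out


def _local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the efficiency of the neighbor-induced subgraph.

    Subgraph distances come from an iterated boolean-reachability closure
    (one matrix product per additional path length), exact for binary
    graphs. Nodes of similar degree are padded to a common neighborhood size
    and processed together with stacked matrix products.
    """
    n = adj.shape[0]
    degrees = adj.sum(axis=1)
    nodes = np.flatnonzero(degrees >= 2)  # degree <= 1 contributes 0
    if nodes.size == 0:
        return 0.0
    # batch nodes of similar degree together: padding waste stays bounded
    order = nodes[np.argsort(degrees[nodes], kind="stable")]
    ks = degrees[order].astype(int)
    total = 0.0
    start = 0
    while start < order.size:
        k_lo = ks[start]
        stop = start
        while stop < order.size and ks[stop] <= max(k_lo * 1.3, k_lo + 4):
            stop += 1
        total += _eloc_batched(adj, order[start:stop], ks[start:stop],
                               int(ks[stop - 1]))
        start = stop
    return total / n


def _eloc_batched(adj, nodes, ks, kmax) -> float:
    m = nodes.size
    idx = np.zeros((m, kmax), dtype=int)
    valid = np.zeros((m, kmax), dtype=bool)
    for row, v in enumerate(nodes):
        nb = np.flatnonzero(adj[v])
        idx[row, :nb.size] = nb
        valid[row, :nb.size] = True
    sub = adj[idx[:, :, None], idx[:, None, :]]
    sub &= valid[:, :, None] & valid[:, None, :]
    sub_f = sub.astype(np.float32)
    inv = sub.astype(np.float64)  # float64: exact 1/d accumulation
    reach = sub_f + np.eye(kmax, dtype=np.float32)
    d = 1
    while d <= kmax:
        nxt = np.matmul(reach, sub_f) > 0  # reachability only
        new = nxt & (reach == 0)
        if not new.any():
            break
        d += 1
        inv[new] = 1.0 / d
        reach[new] = 1.0
    per_node = inv.sum(axis=(1, 2)) / (ks * (ks - 1))
    return float(per_node.sum())


def compute_global_metrics(graph: ThresholdedGraph,
                           metrics=("Cp", "Lp", "Eglob", "Eloc")) -> dict:
    """Compute global metrics of one thresholded graph.

    Conventions: Cp uses per-node clustering with 0 for degree < 2; Lp averages
    shortest-path lengths over *connected* pairs only (NaN if there are none);
    Eglob treats disconnected pairs as zero efficiency; Eloc is the mean over
    all nodes (degree <= 1 contributing 0) of the neighbor-subgraph efficiency.
    """
    if graph.n_nodes < 2:
        raise ValueError("graph metrics need at least 2 nodes")
    adj = graph.adjacency
    out = _closure_metrics(adj, need_cp="Cp" in metrics,
                           need_paths="Lp" in metrics or "Eglob" in metrics)
    out = {m: out[m] for m in out if m in metrics}
    if "Eloc" in metrics:
        out["Eloc"] = _local_efficiency(adj)
    return out


def betweenness_centrality(graph: ThresholdedGraph) -> np.ndarray:
    """Unnormalized nodal betweenness (each unordered (s, t) pair once)."""
    return np.asarray(graph.graph.betweenness(directed=False), dtype=float)


def _double_edge_swap(edges: np.ndarray, n_nodes: int, n_attempts: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorized degree-preserving double-edge swap.

    Proposals are drawn and validated in batches: a proposal picks two
    distinct edges (a, b), (c, d) with four distinct endpoints and replaces
    them by (a, d), (b, c) (or (a, c), (b, d), chosen at random) provided the
    new edges are absent from the graph. Within a batch, proposals that touch
    the same edge slot or would create the same new edge are dropped
    (conservative rejection keeps the result simple and exact). Degree
    sequence, node and edge counts are preserved by construction.
    """
    n_edges = edges.shape[0]
    out = edges.copy()
    if n_edges < 2:
        return out
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[out[:, 0], out[:, 1]] = True
    adj |= adj.T
    done = 0
    half = n_edges // 2
    while done < n_attempts:
        # pair up edge slots through a random permutation: proposals within a
        # batch are slot-disjoint by construction
        perm = rng.permutation(n_edges)
        b = min(half, n_attempts - done)
        done += b
        ei, ej = perm[:b], perm[half:half + b]
        orient = rng.integers(0, 2, size=b).astype(bool)
        a, bb = out[ei, 0], out[ei, 1]
        c, d = out[ej, 0], out[ej, 1]
        p = np.where(orient, d, c)  # new partner of a
        q = np.where(orient, c, d)  # new partner of bb
        ok = ((a != c) & (a != d) & (bb != c) & (bb != d)
              & ~adj[a, p] & ~adj[bb, q])
        if not ok.any():
            continue
        keep = np.flatnonzero(ok)
        # unique new edges within the batch
        key1 = np.minimum(a[keep], p[keep]) * n_nodes + np.maximum(a[keep], p[keep])
        key2 = np.minimum(bb[keep], q[keep]) * n_nodes + np.maximum(bb[keep], q[keep])
        cnt = np.bincount(key1, minlength=n_nodes * n_nodes)
        cnt += np.bincount(key2, minlength=n_nodes * n_nodes)
        clash = (cnt[key1] > 1) | (cnt[key2] > 1)
        keep = keep[~clash]
        if keep.size == 0:
            continue
        ai, bi, ci, di = a[keep], bb[keep], c[keep], d[keep]
        pi, qi = p[keep], q[keep]
        adj[ai, bi] = adj[bi, ai] = False
        adj[ci, di] = adj[di, ci] = False
        adj[ai, pi] = adj[pi, ai] = True
        adj[bi, qi] = adj[qi, bi] = True
        out[ei[keep], 0] = np.minimum(ai, pi)
        out[ei[keep], 1] = np.maximum(ai, pi)
        out[ej[keep], 0] = np.minimum(bi, qi)
        out[ej[keep], 1] = np.maximum(bi, qi)
    return out


def rewire_null(graph: ThresholdedGraph, swaps_per_edge: int = 10,
                seed: int | None = None) -> ThresholdedGraph:
    """Degree-preserving double-edge-swap randomization of a graph.

    Attempts ``swaps_per_edge * n_edges`` swaps; each accepted swap exchanges
    the endpoints of two independent edges, so the degree sequence, node count
    and edge count are exactly preserved and no self-loops or multi-edges are
    introduced. Seeded and reproducible.
    """
    if swaps_per_edge <= 0:
        raise ValueError("swaps_per_edge must be positive")
    rng = np.random.default_rng(seed)
    edges = _double_edge_swap(graph.edges, graph.n_nodes,
                              int(swaps_per_edge * graph.n_edges), rng)
    return ThresholdedGraph(graph.n_nodes, graph.sparsity, edges)


def small_world_indices(graph: ThresholdedGraph, n_nulls: int = 100,
                        seed: int | None = None, swaps_per_edge: int = 10,
                        nulls=None) -> dict:
    """Small-world indices against degree-preserving null networks.

    gamma = Cp / mean(Cp of nulls), lambda = Lp / mean(Lp of nulls),
    sigma = gamma / lambda. ``nulls`` may inject pre-built reference graphs
    (e.g. for testing); otherwise ``n_nulls`` rewired graphs are generated
    from ``seed``.
    """
    own = compute_global_metrics(graph, metrics=("Cp", "Lp"))
    null_cp = []
    null_lp = []
    if nulls is None:
        if n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be positive")
        seeds = np.random.SeedSequence(seed).generate_state(n_nulls) >> 1
        n_swaps = int(swaps_per_edge * graph.n_edges)
        for s in seeds:
            rng = np.random.default_rng(int(s))
            null_edges = _double_edge_swap(graph.edges, graph.n_nodes,
                                           n_swaps, rng)
            null_adj = np.zeros((graph.n_nodes, graph.n_nodes), dtype=bool)
            null_adj[null_edges[:, 0], null_edges[:, 1]] = True
            null_adj |= null_adj.T
            m = _closure_metrics(null_adj, need_cp=True, need_paths=True)
            null_cp.append(m["Cp"])
            null_lp.append(m["Lp"])
    else:
        for null in nulls:
            m = compute_global_metrics(null, metrics=("Cp", "Lp"))
            null_cp.append(m["Cp"])
            null_lp.append(m["Lp"])
    mean_cp, mean_lp = float(np.mean(null_cp)), float(np.mean(null_lp))
    if mean_cp == 0 or mean_lp == 0 or not np.isfinite(mean_cp * mean_lp):
        raise ValueError("degenerate null model: mean Cp or Lp is 0 or non-finite")
    gamma = own["Cp"] / mean_cp
    lam = own["Lp"] / mean_lp
    return {"gamma": gamma, "lambda": lam, "sigma": gamma / lam}


def auc_over_sparsity(values, thresholds=None) -> float:
    """Trapezoidal area under a metric curve across the sparsity grid."""
    if thresholds is None:
        thresholds = SPARSITY_GRID
    values = np.asarray(values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if values.shape != thresholds.shape:
        raise ValueError(f"curve has {values.size} values for "
                         f"{thresholds.size} thresholds")
    if not np.isfinite(values).all():
        raise ValueError("metric curve contains non-finite values")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return float(np.trapezoid(values, thresholds))


@dataclass(frozen=True)
class MetricCurve:
    """One metric across the sparsity sweep plus its AUC summary."""

    name: str
    thresholds: np.ndarray
    values: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(
            self, "auc", auc_over_sparsity(self.values, self.thresholds))


def analyze_subject(matrix: np.ndarray, grid=None,
                    metrics=("Cp", "Lp", "Eglob", "Eloc"),
                    include_bc: bool = True, n_nulls: int = 0,
                    seed: int | None = None, swaps_per_edge: int = 10) -> dict:
    """Full per-subject topology analysis of one similarity matrix.

    Thresholds over the sparsity grid, computes the requested global metric
    curves (plus gamma/lambda/sigma when ``n_nulls`` > 0) and, if
    ``include_bc``, nodal betweenness curves with their per-region AUC.

    Returns a dict with keys ``curves`` (name -> MetricCurve), ``bc_curves``
    ((n_regions, n_levels) array or None), ``bc_auc`` ((n_regions,) array or
    None) and ``fragmented_levels`` (sparsities whose graph is disconnected).
    """
    if grid is None:
        grid = SPARSITY_GRID
    grid = np.asarray(grid, dtype=float)
    graphs = sparsity_sweep(matrix, grid)
    base = tuple(metrics)
    need = set(base)
    if n_nulls > 0:
        need |= {"Cp", "Lp"}
    series: dict[str, list] = {m: [] for m in need | ({"gamma", "lambda", "sigma"}
                                                      if n_nulls > 0 else set())}
    bc = np.zeros((graphs[0].n_nodes, len(graphs))) if include_bc else None
    fragmented = []
    seed_seq = np.random.SeedSequence(seed)
    level_seeds = seed_seq.generate_state(len(graphs)) >> 1
    for li, graph in enumerate(graphs):
        vals = compute_global_metrics(graph, metrics=tuple(need))
        for m in need:
            series[m].append(vals[m])
        if n_nulls > 0:
            sw = small_world_indices(graph, n_nulls=n_nulls,
                                     seed=int(level_seeds[li]),
                                     swaps_per_edge=swaps_per_edge)
            for m in ("gamma", "lambda", "sigma"):
                series[m].append(sw[m])
        if include_bc:
            bc[:, li] = betweenness_centrality(graph)
        if graph.is_fragmented():
            fragmented.append(float(graph.sparsity))
    wanted = list(base) + (["gamma", "lambda", "sigma"] if n_nulls > 0 else [])
    curves = {m: MetricCurve(m, grid, np.array(series[m])) for m in wanted}
    bc_auc = None
    if include_bc:
        bc_auc = np.array([auc_over_sparsity(bc[r], grid)
                           for r in range(bc.shape[0])])
    return {"curves": curves, "bc_curves": bc, "bc_auc": bc_auc,
            "fragmented_levels": fragmented}
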