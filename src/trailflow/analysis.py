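"""Convergence analysis: path oracles, verdicts, and the potential function.

The convergence theorems are asymptotic ("all the flow eventually goes through
P1"); here they are operationalised finitely: a run has converged when some
s -> d path keeps forward-normalised pheromone >= 1 - tol on every edge for
``patience`` consecutive steps.  Oracles compute the paths the theory predicts
(minimum edge count; minimum compounded leakage) with deterministic
tie-breaking, and ``potential_trace`` evaluates the potential function

    r_min(t) = min over the last L steps of p_ss1/p_ss2 and p_d1d/p_d2d,

L = max(len_P1, len_P2), which never decreases and strictly increases every L
steps under either convergence theorem's hypotheses.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    FlowGraph,
    Trajectory,
    greedy_forward_path,
    path_min_normalized,
    path_leakage,
)

__all__ = [
    "ConvergenceVerdict",
    "PotentialTrace",
    "oracle_shortest_path",
    "oracle_min_leakage_path",
    "detect_convergence",
    "potential_trace",
    "check_vertex_count_bound",
    "parallel_path_pair",
]


# ---------------------------------------------------------------------------
# oracles

def _lex_dijkstra(graph: FlowGraph, vertex_cost) -> tuple:
    """Min-cost s -> d path; ties by fewer vertices, then lexicographic labels.

    ``vertex_cost(v)`` is the non-negative cost of *entering* vertex v (None
    marks v unusable).  Priorities are (total cost, vertex count, label-rank
    sequence), which has optimal substructure, so plain Dijkstra applies.
    """
    s, d = graph.source, graph.destination
    start = (0.0, 1, (graph.rank(s),), (s,))
    heap = [start]
    settled = set()
    while heap:
        cost, nv, _, path = heapq.heappop(heap)
        v = path[-1]
        if v in settled:
            continue
        settled.add(v)
        if v == d:
            return path
        for w in graph.successors(v):
            if w in settled or w in path:
                continue
            c = 0.0 if w == d else vertex_cost(w)
            if c is None:
                continue
            new_path = path + (w,)
            heapq.heappush(
                heap,
                (cost + c + 0.0, nv + 1, tuple(graph.rank(x) for x in new_path), new_path),
            )
    raise ValueError("no directed s->d path exists")


def oracle_shortest_path(graph: FlowGraph) -> tuple:
    """A minimum-edge-count s -> d path (lexicographically smallest on ties)."""
    return _lex_dijkstra(graph, lambda v: 1.0)


def oracle_min_leakage_path(graph: FlowGraph) -> tuple:
    """The s -> d path minimising the compounded leakage l_P.

    Computed as a shortest path under additive vertex weights -log(1 - l_v)
    (vertices with l_v = 1 absorb everything and are unusable); ties broken by
    fewer vertices, then lexicographically.
    """

    def cost(v):
        l = graph.leakage[v]
        if l >= 1.0:
            return None
        return -math.log1p(-l)

    try:
        return _lex_dijkstra(graph, cost)
    except ValueError:
        raise ValueError("every s->d path has leakage 1 (or none exists)")


# ---------------------------------------------------------------------------
# convergence detection

@dataclass
class ConvergenceVerdict:
    converged: bool
    path: tuple | None
    time: int | None
    terminal_flow_fractions: dict

    def __bool__(self):
        return self.converged


def _source_split(graph: FlowGraph, pheromone: np.ndarray) -> dict:
    """Normalised pheromone on the source's outgoing edges at one instant."""
    eids = graph._out[graph.index[graph.source]]
    denom = float(sum(pheromone[i] for i in eids))
    out = {}
    for i in eids:
        out[graph.edges[i]] = float(pheromone[i]) / denom if denom > 0 else math.nan
    return out


def detect_convergence(
    trajectory: Trajectory,
    graph: FlowGraph | None = None,
    tol: float | None = None,
    patience: int | None = None,
) -> ConvergenceVerdict:
    """Scan a recorded trajectory for the finite-time convergence predicate.

    Converged iff some s -> d path held forward-normalised pheromone
    >= 1 - tol on all edges for ``patience`` consecutive steps; the path is
    extracted by following the max-pheromone outgoing edge from s.  Returns a
    non-converged verdict (never raises) when the predicate fails.
    """
    graph = graph or trajectory.graph
    tol = trajectory.config.tol if tol is None else tol
    patience = trajectory.config.patience if patience is None else patience

    streak, cur_path, hit_time, hit_path = 0, None, None, None
    for row, t in zip(trajectory.pheromone, trajectory.times):
        path = greedy_forward_path(graph, row)
        ok = path is not None and path_min_normalized(graph, row, path) >= 1.0 - tol
        if ok and path == cur_path:
            streak += 1
        elif ok:
            cur_path, streak = path, 1
        else:
            cur_path, streak = None, 0
        if streak >= patience and hit_time is None:
            hit_time, hit_path = int(t), cur_path
            break
    fractions = _source_split(graph, trajectory.pheromone[-1]) if len(trajectory.pheromone) else {}
    return ConvergenceVerdict(
        converged=hit_time is not None,
        path=hit_path,
        time=hit_time,
        terminal_flow_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# potential function

def parallel_path_pair(graph: FlowGraph) -> tuple[tuple, tuple]:
    """The two s -> d paths of a two-parallel-paths graph, as vertex tuples."""
    succ = graph.successors(graph.source)
    if len(succ) != 2:
        raise ValueError("graph is not a two-parallel-paths instance")
    paths = []
    for first in succ:
        path = [graph.source, first]
        v = first
        while v != graph.destination:
            nxt = graph.successors(v)
            if len(nxt) != 1:
                raise ValueError("graph is not a two-parallel-paths instance")
            v = nxt[0]
            path.append(v)
        paths.append(tuple(path))
    if len(paths) != 2:
        raise ValueError("graph is not a two-parallel-paths instance")
    return paths[0], paths[1]


@dataclass
class PotentialTrace:
    """Time series of the two pheromone ratios and the potential r_min.

    Ratios are P1-over-P2 on the s-incident and d-incident edge pairs; an
    exhausted competitor (zero denominator) yields +inf, a legal terminal state
    of convergence.  ``r_min[t]`` is defined for t >= L - 1 (NaN before).
    """

    r_ss1: np.ndarray
    r_d1d: np.ndarray
    L: int
    r_min: np.ndarray
    len_p1: int
    len_p2: int

    def is_nondecreasing(self, start: int | None = None) -> bool:
        start = self.L - 1 if start is None else start
        r = self.r_min[start:]
        r = r[~np.isnan(r)]
        r = np.where(np.isinf(r), np.finfo(float).max, r)  # inf is a terminal max
        # tolerance relative to magnitude: ratios can span hundreds of decades
        return bool(np.all(np.diff(r) >= -(1e-9 * np.abs(r[:-1]) + 1e-12)))

    def strictly_increases_every_L(self) -> bool:
        """r_min(t + L) > r_min(t) wherever both are finite."""
        r = self.r_min
        ok = True
        for t in range(self.L - 1, len(r) - self.L):
            a, b = r[t], r[t + self.L]
            if math.isfinite(a) and math.isfinite(b):
                ok = ok and (b > a)
        return ok


def potential_trace(trajectory: Trajectory, p1_path=None) -> PotentialTrace:
    """Evaluate the potential function on a two-parallel-paths run.

    ``p1_path`` designates P1 (the path the scenario predicts: shorter, or
    minimum leakage); by default the minimum-leakage path, falling back to the
    shorter path when leakages tie.
    """
    graph = trajectory.graph
    path_a, path_b = parallel_path_pair(graph)
    if p1_path is not None:
        p1 = tuple(p1_path)
        if p1 == path_a:
            p2 = path_b
        elif p1 == path_b:
            p2 = path_a
        else:
            raise ValueError("p1_path is not one of the graph's two parallel paths")
    else:
        la, lb = path_leakage(graph, path_a), path_leakage(graph, path_b)
        if la != lb:
            p1, p2 = (path_a, path_b) if la < lb else (path_b, path_a)
        else:
            p1, p2 = (path_a, path_b) if len(path_a) <= len(path_b) else (path_b, path_a)

    len1, len2 = len(p1) - 1, len(p2) - 1
    L = max(len1, len2)

    def ratio(num_edge, den_edge):
        num = trajectory.pheromone_series(*num_edge)
        den = trajectory.pheromone_series(*den_edge)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        return r

    r_ss1 = ratio((p1[0], p1[1]), (p2[0], p2[1]))
    r_d1d = ratio((p1[-2], p1[-1]), (p2[-2], p2[-1]))

    T = len(r_ss1)
    r_min = np.full(T, np.nan)
    for t in range(L - 1, T):
        window = np.concatenate([r_ss1[t - L + 1 : t + 1], r_d1d[t - L + 1 : t + 1]])
        r_min[t] = window.min()
    return PotentialTrace(r_ss1=r_ss1, r_d1d=r_d1d, L=L, r_min=r_min, len_p1=len1, len_p2=len2)


# ---------------------------------------------------------------------------
# leakage-vs-vertex-count bound

def check_vertex_count_bound(graph: FlowGraph, eps: float) -> bool:
    """Verify |V(min-leakage path)| <= (1 + eps) * |V(min-vertex path)|.

    Precondition (raises on violation, reporting the offending pair): for all
    vertex pairs u, v with positive leakage, log(1 - l_u) and log(1 - l_v) lie
    within a (1 + eps) factor of each other.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    logs = {
        v: -math.log1p(-graph.leakage[v])
        for v in graph.vertices
        if graph.leakage[v] > 0.0
    }
    items = sorted(logs.items(), key=lambda kv: kv[1])
    if items:
        (u, lo), (v, hi) = items[0], items[-1]
        if hi > (1.0 + eps) * lo * (1.0 + 1e-12):
            raise ValueError(
                f"precondition violated: log(1-l) of {v!r} exceeds that of {u!r} "
                f"by more than a (1+{eps}) factor ({hi:.6g} vs {lo:.6g})"
            )
    min_leak = oracle_min_leakage_path(graph)
    min_vert = oracle_shortest_path(graph)  # min edges == min vertices for s->d paths
    return len(min_leak) <= (1.0 + eps) * len(min_vert) + 1e-12
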