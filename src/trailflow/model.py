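"""Core trail-network model: graphs, state, and the one-step flow/pheromone dynamics.

The model describes a deterministic bidirectional flow of "ants" on a directed
graph G = (V, E) with a source s and a destination d.  Forward flow moves along
edge directions from s toward d, backward flow moves against them from d toward
s.  Each step:

1. new flow is injected at the terminals (``FlowSchedule``),
2. the flow sitting on each vertex divides itself over the incident edges in
   proportion dictated by a pheromone-based decision rule,
3. flow arriving at a vertex is attenuated by the vertex's leakage factor
   (1 - l_v), modelling the loss of ants to exploration,
4. every edge's pheromone is incremented by the flow that crossed it (in either
   direction) and decays by a multiplicative factor delta,
5. forward flow reaching d and backward flow reaching s is absorbed (delivered)
   and leaves the system.

All quantities are continuous and the dynamics is fully deterministic; the only
randomness in the package lives in the graph generators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FlowGraph",
    "SystemState",
    "FlowSchedule",
    "SimulationConfig",
    "Trajectory",
    "initial_state",
    "advance_one_step",
    "simulate",
    "path_leakage",
    "expand_weighted_edges",
    "rescale_state",
    "greedy_forward_path",
    "path_min_normalized",
]


class FlowGraph:
    """Directed graph with terminals s, d and a leakage value per vertex.

    Leakage l_v in [0, 1] is the fraction of flow lost when passing through
    vertex v; the terminals always have leakage 0 (they do not appear in the
    path-leakage product).  Edges are ordered pairs; self-loops and duplicate
    edges are rejected.
    """

    def __init__(
        self,
        vertices: Iterable,
        edges: Iterable[tuple],
        source,
        destination,
        leakage: Mapping | None = None,
    ):
        self.vertices = tuple(vertices)
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate vertex labels")
        self.edges = tuple((u, v) for u, v in edges)
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        vset = set(self.vertices)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown vertex")
        if source == destination:
            raise ValueError("source and destination must differ")
        if source not in vset or destination not in vset:
            raise ValueError("terminals must be vertices of the graph")
        self.source = source
        self.destination = destination

        leak = dict.fromkeys(self.vertices, 0.0)
        if leakage:
            for v, l in leakage.items():
                if v not in vset:
                    raise ValueError(f"leakage given for unknown vertex {v!r}")
                leak[v] = float(l)
        for v, l in leak.items():
            if not (0.0 <= l <= 1.0):
                raise ValueError(f"leakage of {v!r} = {l} outside [0, 1]")
        if leak[source] != 0.0 or leak[destination] != 0.0:
            raise ValueError("terminal vertices must have leakage 0")
        self.leakage = leak

        # index structures used by the vectorised dynamics
        self.index = {v: i for i, v in enumerate(self.vertices)}
        self.edge_index = {e: i for i, e in enumerate(self.edges)}
        self.n = len(self.vertices)
        self.m = len(self.edges)
        self.esrc = np.array([self.index[u] for u, _ in self.edges], dtype=np.intp)
        self.edst = np.array([self.index[v] for _, v in self.edges], dtype=np.intp)
        self.leak_vec = np.array([leak[v] for v in self.vertices])
        self._out: list[list[int]] = [[] for _ in range(self.n)]
        self._in: list[list[int]] = [[] for _ in range(self.n)]
        for ei, (u, v) in enumerate(self.edges):
            self._out[self.index[u]].append(ei)
            self._in[self.index[v]].append(ei)
        self.out_degree = np.array([len(o) for o in self._out])

        # label ordering used for deterministic tie-breaking: natural sort of
        # the labels when they are mutually comparable, string sort otherwise
        try:
            ordered = sorted(self.vertices)
        except TypeError:
            ordered = sorted(self.vertices, key=str)
        self._rank = {v: i for i, v in enumerate(ordered)}

    # -- queries -----------------------------------------------------------
    def out_edges(self, u) -> list[tuple]:
        return [self.edges[i] for i in self._out[self.index[u]]]

    def in_edges(self, v) -> list[tuple]:
        return [self.edges[i] for i in self._in[self.index[v]]]

    def successors(self, u) -> list:
        return [self.edges[i][1] for i in self._out[self.index[u]]]

    def predecessors(self, v) -> list:
        return [self.edges[i][0] for i in self._in[self.index[v]]]

    def has_edge(self, u, v) -> bool:
        return (u, v) in self.edge_index

    def rank(self, v) -> int:
        """Deterministic ordering rank of a vertex label (for tie-breaks)."""
        return self._rank[v]

    def with_leakage(self, leakage: Mapping) -> "FlowGraph":
        return FlowGraph(self.vertices, self.edges, self.source, self.destination, leakage)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for v in self.vertices:
            g.add_node(v, leakage=self.leakage[v])
        g.add_edges_from(self.edges)
        g.graph["source"] = self.source
        g.graph["destination"] = self.destination
        return g

    def is_valid_path(self, path: Sequence) -> bool:
        """True iff `path` is a simple directed s -> d path in this graph."""
        if len(path) < 2 or path[0] != self.source or path[-1] != self.destination:
            return False
        if len(set(path)) != len(path):
            return False
        return all(self.has_edge(u, v) for u, v in zip(path[:-1], path[1:]))

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"FlowGraph(n={self.n}, m={self.m}, "
            f"s={self.source!r}, d={self.destination!r})"
        )


@dataclass
class SystemState:
    """Full system state at an integer time t.

    ``fwd_edge`` / ``bwd_edge`` hold the per-edge flows that moved during the
    transition *into* this state (all zero for an initial state).  Values are
    stored in rescaled units; ``scale_offset`` is the log of the cumulative
    rescaling factor applied so far (0.0 when no rescaling has occurred).
    ``delivered_forward`` / ``delivered_backward`` are the flows absorbed at d
    (forward) and s (backward) on arrival at this state.
    """

    time: int
    pheromone: np.ndarray
    fwd_vertex: np.ndarray
    bwd_vertex: np.ndarray
    fwd_edge: np.ndarray
    bwd_edge: np.ndarray
    scale_offset: float = 0.0
    delivered_forward: float = 0.0
    delivered_backward: float = 0.0

    def pheromone_of(self, graph: FlowGraph, u, v) -> float:
        return float(self.pheromone[graph.edge_index[(u, v)]])


@dataclass(frozen=True)
class FlowSchedule:
    """Injection profile for the terminal flows f_s->(t) and f_d<-(t).

    kind='constant'        : f(t) = base
    kind='multiplicative'  : f(t) = base * alpha**t, alpha > 1
    kind='additive'        : f(t) = base + alpha * t, alpha > 0
    """

    kind: str
    base_forward: float = 1.0
    base_backward: float = 1.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.kind not in ("constant", "multiplicative", "additive"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.base_forward < 0 or self.base_backward < 0:
            raise ValueError("injection bases must be non-negative")
        if self.base_forward == 0 and self.base_backward == 0:
            raise ValueError("at least one injection base must be positive")
        if self.kind == "multiplicative" and not self.alpha > 1:
            raise ValueError("multiplicative schedules require alpha > 1")
        if self.kind == "additive" and not self.alpha > 0:
            raise ValueError("additive schedules require alpha > 0")

    @classmethod
    def constant(cls, forward: float = 1.0, backward: float = 1.0) -> "FlowSchedule":
        return cls("constant", forward, backward)

    @classmethod
    def multiplicative(cls, alpha: float, forward: float = 1.0, backward: float = 1.0):
        return cls("multiplicative", forward, backward, alpha)

    @classmethod
    def additive(cls, alpha: float, forward: float = 1.0, backward: float = 1.0):
        return cls("additive", forward, backward, alpha)

    def _value(self, base: float, t: int, scale_offset: float) -> float:
        if base == 0.0:
            return 0.0
        if self.kind == "multiplicative":
            # evaluated in log space: alpha**t overflows long before the
            # rescaled state does
            return math.exp(math.log(base) + t * math.log(self.alpha) + scale_offset)
        if self.kind == "additive":
            val = base + self.alpha * t
        else:
            val = base
        return val * math.exp(scale_offset) if scale_offset != 0.0 else val

    def forward(self, t: int, scale_offset: float = 0.0) -> float:
        return self._value(self.base_forward, t, scale_offset)

    def backward(self, t: int, scale_offset: float = 0.0) -> float:
        return self._value(self.base_backward, t, scale_offset)


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of a run.

    delta            pheromone decay factor per step, strictly in (0, 1)
    horizon          maximum number of steps
    tol              convergence tolerance: a path counts as converged when
                     every one of its edges holds forward-normalised pheromone
                     >= 1 - tol
    patience         number of consecutive steps the predicate must hold
    rescale_period   how often (in steps) the state is renormalised under
                     multiplicative schedules to avoid overflow
    initial_pheromone  scalar, or mapping edge -> level (unlisted edges get 0)
    seed             recorded for provenance; the dynamics itself is
                     deterministic
    """

    delta: float = 0.9
    horizon: int = 5000
    tol: float = 1e-3
    patience: int = 25
    rescale_period: int = 50
    initial_pheromone: float | Mapping = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie strictly inside (0, 1)")
        if not (0.0 < self.tol < 0.5):
            raise ValueError("tol must lie in (0, 0.5)")
        if self.horizon < 1 or self.patience < 1 or self.rescale_period < 1:
            raise ValueError("horizon, patience and rescale_period must be >= 1")


def initial_state(
    graph: FlowGraph,
    pheromone: float | Mapping | np.ndarray = 1.0,
    fwd_vertex: Mapping | None = None,
    bwd_vertex: Mapping | None = None,
) -> SystemState:
    """Build the t = 0 state: given pheromone, zero flows everywhere."""
    if isinstance(pheromone, Mapping):
        p = np.zeros(graph.m)
        for e, val in pheromone.items():
            p[graph.edge_index[tuple(e)]] = float(val)
    elif np.isscalar(pheromone):
        p = np.full(graph.m, float(pheromone))
    else:
        p = np.asarray(pheromone, dtype=float).copy()
        if p.shape != (graph.m,):
            raise ValueError("pheromone array must have one entry per edge")
    if np.any(p < 0):
        raise ValueError("initial pheromone must be non-negative")
    fv = np.zeros(graph.n)
    bv = np.zeros(graph.n)
    for target, src in ((fv, fwd_vertex), (bv, bwd_vertex)):
        if src:
            for v, val in src.items():
                target[graph.index[v]] = float(val)
    return SystemState(
        time=0,
        pheromone=p,
        fwd_vertex=fv,
        bwd_vertex=bv,
        fwd_edge=np.zeros(graph.m),
        bwd_edge=np.zeros(graph.m),
    )


def advance_one_step(
    graph: FlowGraph,
    state: SystemState,
    rule,
    schedule: FlowSchedule,
    config: SimulationConfig | None = None,
    *,
    apply_leakage: bool = True,
    check: bool = True,
    _warned: set | None = None,
) -> SystemState:
    """Advance the dynamics one step, from time t to t + 1.

    Order of operations within the step: inject new terminal flow, distribute
    vertex flow over incident edges via the decision rule, attenuate arriving
    flow by leakage, update pheromone (add traversing flow, decay by delta),
    absorb flow arriving at the opposite terminal.

    ``apply_leakage=False`` disables the leakage *process* while leaving the
    assigned leakage values available as an objective function (used when
    comparing the dynamics with and without leakage on the same graph).
    """
    cfg = config or SimulationConfig()
    t = state.time
    p = state.pheromone
    if check and (np.any(p < 0) or not np.all(np.isfinite(p))):
        raise FloatingPointError(f"invalid pheromone values at t={t}")

    fv = state.fwd_vertex.copy()
    bv = state.bwd_vertex.copy()
    fv[graph.index[graph.source]] += schedule.forward(t, state.scale_offset)
    bv[graph.index[graph.destination]] += schedule.backward(t, state.scale_offset)
    if check and (np.any(fv < 0) or np.any(bv < 0) or not (np.all(np.isfinite(fv)) and np.all(np.isfinite(bv)))):
        raise FloatingPointError(f"invalid flow values at t={t}")

    warned = _warned if _warned is not None else set()
    ffrac, ffall = rule.forward_edge_fractions(graph, p)
    bfrac, bfall = rule.backward_edge_fractions(graph, p)
    if ffall is not None and np.any(fv[ffall] > 0) and "fwd" not in warned:
        warned.add("fwd")
        logger.warning(
            "t=%d: vertex with positive forward flow but zero total pheromone "
            "on its outgoing edges; splitting uniformly (first occurrence)",
            t,
        )
    if bfall is not None and np.any(bv[bfall] > 0) and "bwd" not in warned:
        warned.add("bwd")
        logger.warning(
            "t=%d: vertex with positive backward flow but zero total pheromone "
            "on its incoming edges; splitting uniformly (first occurrence)",
            t,
        )
    f_edge = fv[graph.esrc] * ffrac
    b_edge = bv[graph.edst] * bfrac

    # flow on a vertex without outgoing (resp. incoming) edges is dropped;
    # pruned DAG instances never hit this, user-supplied cyclic graphs may
    if check and "dead" not in warned:
        stranded = fv[(graph.out_degree == 0)]
        if stranded.size and np.any(stranded > 0):
            warned.add("dead")
            logger.warning("t=%d: forward flow stranded on a dead-end vertex dropped", t)

    leak = graph.leak_vec if apply_leakage else 0.0
    new_fv = (1.0 - leak) * np.bincount(graph.edst, weights=f_edge, minlength=graph.n)
    new_bv = (1.0 - leak) * np.bincount(graph.esrc, weights=b_edge, minlength=graph.n)

    new_p = cfg.delta * (p + f_edge + b_edge)

    d_i = graph.index[graph.destination]
    s_i = graph.index[graph.source]
    delivered_f = float(new_fv[d_i])
    delivered_b = float(new_bv[s_i])
    new_fv[d_i] = 0.0
    new_bv[s_i] = 0.0

    return SystemState(
        time=t + 1,
        pheromone=new_p,
        fwd_vertex=new_fv,
        bwd_vertex=new_bv,
        fwd_edge=f_edge,
        bwd_edge=b_edge,
        scale_offset=state.scale_offset,
        delivered_forward=delivered_f,
        delivered_backward=delivered_b,
    )


def rescale_state(state: SystemState, factor: float) -> SystemState:
    """Multiply all pheromone and flow values by ``factor``.

    The cumulative factor is tracked in ``scale_offset`` so that future
    injections are scaled identically; normalised pheromone and all flow
    *fractions* are unchanged at every future step (the built-in rules are
    ratio-based).  Used to keep multiplicative-schedule runs inside floating
    range.
    """
    if not factor > 0:
        raise ValueError("rescale factor must be positive")
    if factor == 1.0:
        return state
    return SystemState(
        time=state.time,
        pheromone=state.pheromone * factor,
        fwd_vertex=state.fwd_vertex * factor,
        bwd_vertex=state.bwd_vertex * factor,
        fwd_edge=state.fwd_edge * factor,
        bwd_edge=state.bwd_edge * factor,
        scale_offset=state.scale_offset + math.log(factor),
        delivered_forward=state.delivered_forward * factor,
        delivered_backward=state.delivered_backward * factor,
    )


# ---------------------------------------------------------------------------
# convergence predicate helpers (shared by the in-run tracker and the post-hoc
# analysis in trailflow.analysis)

def greedy_forward_path(graph: FlowGraph, pheromone: np.ndarray):
    """Follow the max-pheromone outgoing edge from s; None if d is not reached.

    Ties are broken toward the lower-ranked successor label so the extraction
    is deterministic.
    """
    path = [graph.source]
    seen = {graph.source}
    v = graph.source
    while v != graph.destination:
        eids = graph._out[graph.index[v]]
        if not eids:
            return None
        best = max(
            eids,
            key=lambda ei: (pheromone[ei], -graph.rank(graph.edges[ei][1])),
        )
        v = graph.edges[best][1]
        if v in seen:
            return None
        seen.add(v)
        path.append(v)
    return tuple(path)


def path_min_normalized(graph: FlowGraph, pheromone: np.ndarray, path: Sequence) -> float:
    """Minimum over the path's edges of the forward-normalised pheromone."""
    worst = 1.0
    for u, v in zip(path[:-1], path[1:]):
        eids = graph._out[graph.index[u]]
        denom = float(sum(pheromone[i] for i in eids))
        if denom <= 0:
            return 0.0
        worst = min(worst, float(pheromone[graph.edge_index[(u, v)]]) / denom)
    return worst


class _ConvergenceTracker:
    """Streak counter for the finite-time convergence predicate."""

    def __init__(self, graph: FlowGraph, tol: float, patience: int):
        self.graph = graph
        self.tol = tol
        self.patience = patience
        self.streak = 0
        self.path: tuple | None = None
        self.converged_at: int | None = None

    def update(self, time: int, pheromone: np.ndarray) -> bool:
        path = greedy_forward_path(self.graph, pheromone)
        ok = path is not None and path_min_normalized(self.graph, pheromone, path) >= 1.0 - self.tol
        if ok and path == self.path:
            self.streak += 1
        elif ok:
            self.path = path
            self.streak = 1
        else:
            self.path = None
            self.streak = 0
        if self.streak >= self.patience and self.converged_at is None:
            self.converged_at = time
            return True
        return False


@dataclass
class Trajectory:
    """Recorded run: per-step pheromone plus delivered flow, and the verdict.

    ``pheromone`` has shape (T + 1, m): row k is the state at time k (row 0 is
    the initial state), in rescaled units (``scale_offsets`` row-aligned).
    Normalised pheromone and pheromone *ratios* are invariant to rescaling.
    """

    graph: FlowGraph
    times: np.ndarray
    pheromone: np.ndarray
    delivered_forward: np.ndarray
    delivered_backward: np.ndarray
    scale_offsets: np.ndarray
    converged_path: tuple | None
    convergence_time: int | None
    config: SimulationConfig
    final_state: SystemState | None = None

    def pheromone_series(self, u, v) -> np.ndarray:
        return self.pheromone[:, self.graph.edge_index[(u, v)]]

    def normalized_forward_series(self, u, v) -> np.ndarray:
        """Forward-normalised pheromone of edge (u, v) over time."""
        eids = self.graph._out[self.graph.index[u]]
        denom = self.pheromone[:, eids].sum(axis=1)
        num = self.pheromone_series(u, v)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom > 0, num / denom, 0.0)
        return out

    def to_frame(self):
        """One row per step: t, delivered flows, per-edge (normalised) pheromone."""
        import pandas as pd

        data = {
            "t": self.times,
            "delivered_forward": self.delivered_forward,
            "delivered_backward": self.delivered_backward,
        }
        for u, v in self.graph.edges:
            data[f"p[{u}->{v}]"] = self.pheromone_series(u, v)
            data[f"pbar[{u}->{v}]"] = self.normalized_forward_series(u, v)
        return pd.DataFrame(data)


def simulate(
    graph: FlowGraph,
    rule,
    schedule: FlowSchedule,
    config: SimulationConfig | None = None,
    *,
    apply_leakage: bool = True,
    stop_on_convergence: bool = True,
    record: bool = True,
) -> Trajectory:
    """Run the dynamics up to the horizon (or early convergence).

    Convergence is declared when some s -> d path keeps forward-normalised
    pheromone >= 1 - tol on all of its edges for ``patience`` consecutive
    steps; the path is extracted by following the max-pheromone outgoing edge
    from s.
    """
    cfg = config or SimulationConfig()
    state = initial_state(graph, cfg.initial_pheromone)
    tracker = _ConvergenceTracker(graph, cfg.tol, cfg.patience)
    warned: set = set()  # rate-limits degenerate-case warnings to once per run

    times = [0]
    p_hist = [state.pheromone.copy()] if record else None
    dv_f = [0.0]
    dv_b = [0.0]
    offsets = [0.0]

    for t in range(cfg.horizon):
        state = advance_one_step(
            graph, state, rule, schedule, cfg, apply_leakage=apply_leakage, _warned=warned
        )
        if record:
            p_hist.append(state.pheromone.copy())
        times.append(state.time)
        dv_f.append(state.delivered_forward)
        dv_b.append(state.delivered_backward)
        offsets.append(state.scale_offset)

        hit = tracker.update(state.time, state.pheromone)
        if hit and stop_on_convergence:
            break

        if (
            schedule.kind == "multiplicative"
            and state.time % cfg.rescale_period == 0
        ) or state.pheromone.max() > 1e250:
            peak = state.pheromone.max()
            if peak > 0:
                state = rescale_state(state, 1.0 / peak)
                offsets[-1] = state.scale_offset

    return Trajectory(
        graph=graph,
        times=np.asarray(times),
        pheromone=np.asarray(p_hist) if record else np.zeros((0, graph.m)),
        delivered_forward=np.asarray(dv_f),
        delivered_backward=np.asarray(dv_b),
        scale_offsets=np.asarray(offsets),
        converged_path=tracker.path if tracker.converged_at is not None else None,
        convergence_time=tracker.converged_at,
        config=cfg,
        final_state=state,
    )


# ---------------------------------------------------------------------------
# path utilities

def path_leakage(graph: FlowGraph, path: Sequence) -> float:
    """Leakage l_P = 1 - prod over internal vertices of (1 - l_v).

    The fraction of flow lost in transit along the s -> d path ``path``;
    terminals are excluded from the product.
    """
    if not graph.is_valid_path(path):
        raise ValueError(f"{list(path)!r} is not a directed s->d path in the graph")
    prod = 1.0
    for v in path[1:-1]:
        prod *= 1.0 - graph.leakage[v]
    return 1.0 - prod


def expand_weighted_edges(graph: FlowGraph, lengths: Mapping[tuple, int]) -> FlowGraph:
    """Replace each edge of integer length k >= 2 by a chain of k unit edges.

    The k - 1 fresh intermediate vertices carry leakage 0, so the chain leaks
    exactly as much as the original weighted edge (nothing).  Edges without an
    entry in ``lengths`` (or with length 1) are kept as they are.
    """
    for e, k in lengths.items():
        if tuple(e) not in graph.edge_index:
            raise ValueError(f"length given for unknown edge {e!r}")
        if not (isinstance(k, (int, np.integer)) and k >= 1):
            raise ValueError(f"edge length must be a positive integer, got {k!r}")

    vertices = list(graph.vertices)
    edges = []
    leakage = dict(graph.leakage)
    for u, v in graph.edges:
        k = int(lengths.get((u, v), 1))
        if k == 1:
            edges.append((u, v))
            continue
        chain = [u]
        for i in range(1, k):
            w = f"{u}~{v}~{i}"
            while w in leakage:  # avoid accidental collisions with user labels
                w += "_"
            vertices.append(w)
            leakage[w] = 0.0
            chain.append(w)
        chain.append(v)
        edges.extend(zip(chain[:-1], chain[1:]))
    return FlowGraph(vertices, edges, graph.source, graph.destination, leakage)
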