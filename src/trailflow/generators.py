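"""Seeded graph generators for the simulation families, plus pruning.

Three random families emulate junction networks in vegetation:

* ``gen_gnp``       -- G(n, p) with edges oriented low label -> high label
                       (a DAG), s = 1, d = n;
* ``gen_gnp_local`` -- same, but an edge {i, j} is only allowed when
                       |i - j| <= k, reflecting the local physical structure
                       of branches and vines;
* ``gen_grid``      -- n x n lattice with edges directed right and down,
                       s = top-left corner, d = bottom-right corner.

``gen_parallel_paths`` builds the two-parallel-paths gadgets used by the
convergence theorems and counterexamples.  Generators condition on the
existence of a directed s -> d path (resample up to a retry budget) and prune
to the subgraph of vertices/edges lying on at least one s -> d path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .model import FlowGraph

__all__ = [
    "GeneratorSpec",
    "LeakageSpec",
    "gen_parallel_paths",
    "gen_gnp",
    "gen_gnp_local",
    "gen_grid",
    "assign_leakage",
    "prune_to_sd",
]

DEFAULT_RETRY_BUDGET = 100


@dataclass(frozen=True)
class LeakageSpec:
    """Constant leakage, or i.i.d. uniform on [0, l_max], at internal vertices."""

    kind: str  # 'constant' | 'uniform'
    value: float

    def __post_init__(self):
        if self.kind not in ("constant", "uniform"):
            raise ValueError(f"unknown leakage kind {self.kind!r}")
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("leakage parameter must lie in [0, 1]")

    @classmethod
    def parse(cls, text) -> "LeakageSpec":
        """Parse 'constant:0.1' / 'uniform:0.3' (or a bare number = constant)."""
        if isinstance(text, LeakageSpec):
            return text
        if isinstance(text, (int, float)):
            return cls("constant", float(text))
        kind, _, val = str(text).partition(":")
        return cls(kind, float(val))


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a random instance family."""

    family: str  # 'gnp' | 'gnp_local' | 'grid' | 'parallel_paths'
    n: int = 20
    p: float = 0.3
    k: int = 5
    path_lengths: tuple = (2, 3)
    leakage: LeakageSpec | None = None

    def __post_init__(self):
        if self.family not in ("gnp", "gnp_local", "grid", "parallel_paths"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "gnp_local" and self.k < 1:
            raise ValueError("gnp_local requires k >= 1")
        if self.family == "parallel_paths" and tuple(self.path_lengths) == (1, 1):
            raise ValueError("parallel paths of lengths (1, 1) would duplicate s->d")

    def generate(self, seed: int) -> FlowGraph:
        if self.family == "gnp":
            g = gen_gnp(self.n, self.p, seed)
        elif self.family == "gnp_local":
            g = gen_gnp_local(self.n, self.p, self.k, seed)
        elif self.family == "grid":
            g = gen_grid(self.n)
        else:
            l1, l2 = self.path_lengths
            g = gen_parallel_paths(l1, l2)
        if self.leakage is not None:
            g = assign_leakage(g, self.leakage, seed)
        return g


def gen_parallel_paths(
    len1: int,
    len2: int,
    leakages1: Sequence[float] | None = None,
    leakages2: Sequence[float] | None = None,
) -> FlowGraph:
    """Two internally vertex-disjoint directed s -> d paths of the given lengths.

    Internal vertices of path i are labelled 'a1', 'a2', ... (first path) and
    'b1', ... (second); ``leakages1``/``leakages2`` assign their leakage values
    (default 0).  Lengths are edge counts; (1, 1) is rejected because both
    paths would be the same single edge.
    """
    if len1 < 1 or len2 < 1:
        raise ValueError("path lengths must be >= 1")
    if len1 == 1 and len2 == 1:
        raise ValueError("paths of lengths (1, 1) would duplicate the edge s->d")

    def build(prefix, length, leaks):
        internal = [f"{prefix}{i}" for i in range(1, length)]
        if leaks is None:
            leaks = [0.0] * len(internal)
        if len(leaks) != len(internal):
            raise ValueError(
                f"expected {len(internal)} leakage values for the {prefix}-path, "
                f"got {len(leaks)}"
            )
        chain = ["s", *internal, "d"]
        return internal, dict(zip(internal, leaks)), list(zip(chain[:-1], chain[1:]))

    int1, leak1, edges1 = build("a", len1, leakages1)
    int2, leak2, edges2 = build("b", len2, leakages2)
    vertices = ["s", *int1, *int2, "d"]
    leakage = {"s": 0.0, "d": 0.0, **leak1, **leak2}
    return FlowGraph(vertices, edges1 + edges2, "s", "d", leakage)


def _gen_gnp_family(
    n: int, p: float, k: int | None, seed: int, retry_budget: int
) -> FlowGraph:
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)  # candidate pairs (i < j), fixed order
    allowed = np.ones(iu.size, dtype=bool) if k is None else (ju - iu) <= k
    for _ in range(retry_budget):
        # one draw per unordered pair regardless of the locality mask, so the
        # same seed yields the same graph whenever the mask is vacuous
        draws = rng.random(iu.size)
        keep = (draws < p) & allowed
        edges = [(int(i) + 1, int(j) + 1) for i, j in zip(iu[keep], ju[keep])]
        graph = FlowGraph(range(1, n + 1), edges, 1, n)
        if _has_sd_path(graph):
            return prune_to_sd(graph)
    raise RuntimeError(
        f"no s->d path found in {retry_budget} attempts "
        f"(n={n}, p={p}, k={k}); increase p or the retry budget"
    )


def gen_gnp(n: int, p: float, seed: int, retry_budget: int = DEFAULT_RETRY_BUDGET) -> FlowGraph:
    """G(n, p) with edges oriented i -> j for i < j; s = 1, d = n; pruned."""
    return _gen_gnp_family(n, p, None, seed, retry_budget)


def gen_gnp_local(
    n: int, p: float, k: int, seed: int, retry_budget: int = DEFAULT_RETRY_BUDGET
) -> FlowGraph:
    """G(n, p) restricted to pairs with |i - j| <= k (local physical structure)."""
    if k < 1:
        raise ValueError("locality bound k must be >= 1")
    return _gen_gnp_family(n, p, k, seed, retry_budget)


def gen_grid(n: int) -> FlowGraph:
    """n x n lattice, edges directed right and down; s top-left, d bottom-right.

    Vertices are labelled 1..n*n in row-major order; every vertex lies on an
    s -> d path, so no pruning is needed.
    """
    if n < 2:
        raise ValueError("grid requires n >= 2")

    def lab(r, c):
        return r * n + c + 1

    edges = []
    for r in range(n):
        for c in range(n):
            if c + 1 < n:
                edges.append((lab(r, c), lab(r, c + 1)))
            if r + 1 < n:
                edges.append((lab(r, c), lab(r + 1, c)))
    return FlowGraph(range(1, n * n + 1), edges, 1, n * n)


def assign_leakage(graph: FlowGraph, spec, seed: int | None = None) -> FlowGraph:
    """Assign leakage to internal vertices per spec; terminals always get 0."""
    spec = LeakageSpec.parse(spec)
    internal = [v for v in graph.vertices if v not in (graph.source, graph.destination)]
    if spec.kind == "constant":
        values = {v: spec.value for v in internal}
    else:
        rng = np.random.default_rng(seed)
        draws = rng.uniform(0.0, spec.value, size=len(internal))
        values = dict(zip(internal, draws.tolist()))
    values[graph.source] = 0.0
    values[graph.destination] = 0.0
    return graph.with_leakage(values)


def _has_sd_path(graph: FlowGraph) -> bool:
    return nx.has_path(graph.to_networkx(), graph.source, graph.destination)


def prune_to_sd(graph: FlowGraph) -> FlowGraph:
    """Restrict to vertices and edges lying on at least one directed s -> d path.

    A vertex survives iff it is reachable from s and reaches d; every edge
    between two survivors then lies on some s -> d path.  Idempotent.
    """
    g = graph.to_networkx()
    if not nx.has_path(g, graph.source, graph.destination):
        raise ValueError("graph has no directed s->d path")
    from_s = nx.descendants(g, graph.source) | {graph.source}
    to_d = nx.ancestors(g, graph.destination) | {graph.destination}
    keep = from_s & to_d
    vertices = [v for v in graph.vertices if v in keep]
    edges = [(u, v) for u, v in graph.edges if u in keep and v in keep]
    leakage = {v: graph.leakage[v] for v in vertices}
    return FlowGraph(vertices, edges, graph.source, graph.destination, leakage)
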