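"""Decision rules: how flow sitting on a vertex divides over sibling edges.

A decision rule maps the pheromone levels of the candidate edges (outgoing
edges for forward flow, incoming for backward flow) to non-negative fractions
summing to 1.  Built-ins:

* the linear rule -- split proportional to pheromone (the unique member of the
  g-rule family with guaranteed convergence to shortest / minimum-leakage
  paths),
* power rules -- split proportional to pheromone**k (quadratic k=2, the
  near-linear k=1.1),
* the family of g-rules on degree-<=2 vertices: a monotone g on [0, 1/2] with
  g(0) = 0 and g(1/2) = 1/2 receives the smaller normalised pheromone x and
  returns the flow fraction of that edge.

All built-ins depend only on pheromone *ratios*, so they are invariant to a
joint rescaling of the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "linear_split",
    "power_split",
    "normalized_pheromone",
    "g_family_split",
    "validate_g_rule",
    "GRuleDiagnostics",
    "DecisionRule",
    "LinearRule",
    "PowerRule",
    "GFamilyRule",
    "linear_g",
    "quadratic_g",
    "power_g",
    "rule_from_spec",
]


def _as_array(pheromones) -> np.ndarray:
    p = np.asarray(pheromones, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d sequence of pheromone levels")
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("pheromone levels must be finite and non-negative")
    return p


def linear_split(pheromones: Sequence[float]) -> np.ndarray:
    """Fractions proportional to pheromone: p_i / sum_j p_j."""
    p = _as_array(pheromones)
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero pheromone: linear split undefined")
    return p / total


def power_split(pheromones: Sequence[float], exponent: float) -> np.ndarray:
    """Fractions proportional to pheromone**exponent (k=2: quadratic rule)."""
    if not exponent > 0:
        raise ValueError("exponent must be positive")
    p = _as_array(pheromones)
    peak = p.max()
    if peak <= 0:
        raise ValueError("all-zero pheromone: power split undefined")
    w = (p / peak) ** exponent  # normalise first so huge levels cannot overflow
    return w / w.sum()


def normalized_pheromone(graph, pheromone, edge: tuple, direction: str) -> float:
    """Normalised pheromone of an edge among its sibling edges.

    direction='forward' normalises over the outgoing edges of the edge's tail;
    'backward' over the incoming edges of its head.  Pheromone itself carries
    no direction -- only the normalisation does.
    """
    u, v = edge
    if direction == "forward":
        sibs = graph.out_edges(u)
    elif direction == "backward":
        sibs = graph.in_edges(v)
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    if isinstance(pheromone, np.ndarray):
        get = lambda e: float(pheromone[graph.edge_index[e]])
    else:
        get = lambda e: float(pheromone[e])
    denom = sum(get(e) for e in sibs)
    if denom <= 0:
        raise ValueError(f"zero sibling pheromone at edge {edge!r} ({direction})")
    return get((u, v)) / denom


def g_family_split(g: Callable[[float], float], pheromones: Sequence[float]) -> np.ndarray:
    """Split flow over exactly two sibling edges using a g-rule.

    The edge with the smaller normalised pheromone x gets fraction g(x), the
    other 1 - g(x); equal levels split evenly for every valid g.
    """
    p = _as_array(pheromones)
    if p.size == 1:
        return np.ones(1)
    if p.size != 2:
        raise ValueError(
            "g-rules are defined for degree 1 and 2 vertices only; "
            f"got {p.size} candidate edges (use a power rule instead)"
        )
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero pheromone: g-rule split undefined")
    x = p.min() / total
    if p[0] == p[1]:
        return np.array([0.5, 0.5])
    lo = float(np.clip(g(x), 0.0, 1.0))
    out = np.empty(2)
    i_min = int(np.argmin(p))
    out[i_min] = lo
    out[1 - i_min] = 1.0 - lo
    return out


@dataclass
class GRuleDiagnostics:
    passed: bool
    messages: list = field(default_factory=list)

    def __bool__(self):
        return self.passed


def validate_g_rule(
    g: Callable[[float], float], n_grid: int = 1001, tol: float = 1e-12
) -> GRuleDiagnostics:
    """Check the family-membership conditions of a g-rule.

    Requires g(0) = 0 and g(1/2) = 1/2 (to tolerance) and monotone
    non-decreasing behaviour, checked on a dense grid over [0, 1/2].
    """
    msgs = []
    g0 = g(0.0)
    gh = g(0.5)
    if abs(g0) > tol:
        msgs.append(f"g(0) = {g0} != 0")
    if abs(gh - 0.5) > tol:
        msgs.append(f"g(1/2) = {gh} != 1/2")
    xs = np.linspace(0.0, 0.5, n_grid)
    ys = np.array([g(x) for x in xs])
    if np.any(np.diff(ys) < -tol):
        i = int(np.argmax(np.diff(ys) < -tol))
        msgs.append(f"g not monotone: g({xs[i]:.4f}) > g({xs[i + 1]:.4f})")
    if np.any(ys < -tol) or np.any(ys > 1 + tol):
        msgs.append("g leaves the range [0, 1]")
    return GRuleDiagnostics(passed=not msgs, messages=msgs)


# ---------------------------------------------------------------------------
# rule objects used by the simulator


class DecisionRule:
    """Contract: map sibling-edge pheromone levels to flow fractions.

    ``split`` is the scalar form used at a single vertex.  The
    ``*_edge_fractions`` methods return a per-edge fraction array for the whole
    graph plus the boolean vertex mask where the all-zero-pheromone uniform
    fallback fired (None when it did not).
    """

    name: str = "abstract"

    def split(self, pheromones: Sequence[float]) -> np.ndarray:
        raise NotImplementedError

    # generic (loop) implementations; PowerRule overrides with vectorised ones
    def _group_fractions(self, graph, pheromone, groups, heads):
        frac = np.zeros(graph.m)
        fallback = np.zeros(graph.n, dtype=bool)
        for vi in range(graph.n):
            eids = groups[vi]
            if not eids:
                continue
            local = pheromone[eids]
            if local.sum() <= 0:
                frac[eids] = 1.0 / len(eids)
                fallback[vi] = True
            else:
                frac[eids] = self.split(local)
        return frac, (fallback if fallback.any() else None)

    def forward_edge_fractions(self, graph, pheromone):
        return self._group_fractions(graph, pheromone, graph._out, graph.esrc)

    def backward_edge_fractions(self, graph, pheromone):
        return self._group_fractions(graph, pheromone, graph._in, graph.edst)


class PowerRule(DecisionRule):
    """Split proportional to pheromone**exponent; exponent 1 is the linear rule."""

    def __init__(self, exponent: float):
        if not exponent > 0:
            raise ValueError("exponent must be positive")
        self.exponent = float(exponent)
        self.name = "linear" if exponent == 1.0 else f"power({exponent:g})"

    def split(self, pheromones):
        if self.exponent == 1.0:
            return linear_split(pheromones)
        return power_split(pheromones, self.exponent)

    def _vector_fractions(self, graph, pheromone, owner, n):
        p = pheromone
        if self.exponent != 1.0:
            peak = p.max()
            w = (p / peak) ** self.exponent if peak > 0 else p.copy()
        else:
            w = p
        denom = np.bincount(owner, weights=w, minlength=n)
        safe = denom[owner]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(safe > 0, w / np.where(safe > 0, safe, 1.0), 0.0)
        zero_mask = denom <= 0
        fallback = None
        if np.any(zero_mask):
            deg = np.bincount(owner, minlength=n).astype(float)
            bad = zero_mask & (deg > 0)
            if np.any(bad):
                sel = bad[owner]
                frac[sel] = 1.0 / deg[owner][sel]
                fallback = bad
        return frac, fallback

    def forward_edge_fractions(self, graph, pheromone):
        return self._vector_fractions(graph, pheromone, graph.esrc, graph.n)

    def backward_edge_fractions(self, graph, pheromone):
        return self._vector_fractions(graph, pheromone, graph.edst, graph.n)


class LinearRule(PowerRule):
    """The linear decision rule: flow proportional to pheromone."""

    def __init__(self):
        super().__init__(1.0)


class GFamilyRule(DecisionRule):
    """A rule from the degree-<=2 family, given by its g on [0, 1/2].

    Validates g on construction; errors at simulation time if the graph has a
    vertex of forward out-degree or backward in-degree above 2.
    """

    def __init__(self, g: Callable[[float], float], name: str = "g-rule", validate: bool = True):
        if validate:
            diag = validate_g_rule(g)
            if not diag:
                raise ValueError(f"invalid g-rule: {'; '.join(diag.messages)}")
        self.g = g
        self.name = name

    def split(self, pheromones):
        return g_family_split(self.g, pheromones)


def linear_g(x: float) -> float:
    return x


def quadratic_g(x: float) -> float:
    """g of the quadratic rule on two edges: x^2 / (x^2 + (1-x)^2)."""
    return x * x / (x * x + (1.0 - x) ** 2)


def power_g(exponent: float) -> Callable[[float], float]:
    """g of the two-edge power rule: x^k / (x^k + (1-x)^k)."""

    def g(x: float) -> float:
        if x <= 0.0:
            return 0.0
        return x**exponent / (x**exponent + (1.0 - x) ** exponent)

    g.__name__ = f"power_g_{exponent:g}"
    return g


_NAMED_G = {"linear": linear_g, "quadratic": quadratic_g}


def rule_from_spec(spec) -> DecisionRule:
    """Build a rule from a config mapping or shorthand string.

    Accepted forms: "linear" | {"rule": "linear"} | {"rule": "power",
    "exponent": 2} | {"rule": "g", "g": "quadratic"}.
    """
    if isinstance(spec, str):
        spec = {"rule": spec}
    if isinstance(spec, DecisionRule):
        return spec
    kind = spec.get("rule")
    if kind == "linear":
        return LinearRule()
    if kind == "power":
        return PowerRule(float(spec["exponent"]))
    if kind == "g":
        gname = spec.get("g", "linear")
        if callable(gname):
            return GFamilyRule(gname)
        if gname in _NAMED_G:
            return GFamilyRule(_NAMED_G[gname], name=f"g({gname})")
        raise ValueError(f"unknown g-rule name {gname!r}")
    raise ValueError(f"unknown rule spec {spec!r}")
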