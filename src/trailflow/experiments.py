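"""Experiment harness: sweeps, paired comparisons, and counterexamples.

Reproduces the model's headline phenomena:

* linear rule + constant flow + leakage  -> minimum-leakage path,
* linear rule + increasing flow, no leakage -> shortest path,
* unidirectional flow breaks both guarantees (an initial-pheromone swap flips
  the outcome),
* every nonlinear rule of the degree-2 family admits an instance where the
  dynamics misses the minimum-leakage (or shortest) path,
* yet with nonlinear rules the forces of increasing flow and leakage still
  usually shorten (or de-leak) the path found, relative to running without
  the force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .analysis import (
    detect_convergence,
    oracle_min_leakage_path,
    oracle_shortest_path,
)
from .generators import GeneratorSpec, gen_parallel_paths
from .model import (
    FlowGraph,
    FlowSchedule,
    SimulationConfig,
    Trajectory,
    greedy_forward_path,
    path_leakage,
    simulate,
)
from .rules import DecisionRule, GFamilyRule, LinearRule, validate_g_rule

__all__ = [
    "ExperimentRecord",
    "ComparisonSummary",
    "run_simulation",
    "batch_compare",
    "UnidirectionalDemo",
    "counterexample_unidirectional",
    "NonlinearDemo",
    "counterexample_nonlinear",
]


@dataclass
class ExperimentRecord:
    """Outcome of one run; path length and leakage are recomputed from the
    graph, never trusted from the simulator."""

    instance_id: str
    seed: int | None
    rule: str
    schedule: FlowSchedule
    converged_path: tuple | None
    path_length: int | None
    path_leakage: float | None
    convergence_time: int | None

    @property
    def converged(self) -> bool:
        return self.converged_path is not None


def run_simulation(
    graph: FlowGraph,
    rule: DecisionRule,
    schedule: FlowSchedule,
    config: SimulationConfig | None = None,
    *,
    apply_leakage: bool = True,
    instance_id: str = "run",
    seed: int | None = None,
    record: bool = True,
) -> tuple[Trajectory, ExperimentRecord]:
    """Advance the dynamics to horizon or convergence and summarise the run."""
    traj = simulate(
        graph,
        rule,
        schedule,
        config,
        apply_leakage=apply_leakage,
        record=record,
    )
    path = traj.converged_path
    rec = ExperimentRecord(
        instance_id=instance_id,
        seed=seed,
        rule=rule.name,
        schedule=schedule,
        converged_path=path,
        path_length=(len(path) - 1) if path else None,
        path_leakage=path_leakage(graph, path) if path else None,
        convergence_time=traj.convergence_time,
    )
    return traj, rec


@dataclass
class ComparisonSummary:
    """Paired with-force vs without-force outcomes over seeded instances.

    'Improved-or-equal' means the with-force objective (path length, or
    compounded path leakage) is <= the without-force objective; ties count.
    Instances where either run failed to converge are excluded and counted.
    """

    force: str
    records: list = field(default_factory=list)  # (seed, with_obj, without_obj)
    n_instances: int = 0
    n_excluded: int = 0

    @property
    def n_compared(self) -> int:
        return len(self.records)

    @property
    def fraction_improved_or_equal(self) -> float:
        if not self.records:
            return math.nan
        good = sum(1 for _, w, wo in self.records if w <= wo + 1e-12)
        return good / len(self.records)


def batch_compare(
    spec: GeneratorSpec,
    rule: DecisionRule,
    force: str,
    n_instances: int,
    base_seed: int = 1,
    config: SimulationConfig | None = None,
    alpha: float = 1.05,
    seeds: Sequence[int] | None = None,
) -> ComparisonSummary:
    """Paired runs with and without a force, per instance.

    force='increasing_flow': objective = path length; 'with' uses a
    multiplicative schedule (alpha), 'without' constant injection; the leakage
    process is disabled in both runs.

    force='leakage': objective = compounded path leakage evaluated on the
    assigned leakage values in *both* runs; 'with' applies the leakage process
    during the dynamics, 'without' disables it (the values still define the
    objective).
    """
    if force not in ("increasing_flow", "leakage"):
        raise ValueError(f"unknown force {force!r}")
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    cfg = config or SimulationConfig()
    if seeds is None:
        seeds = [base_seed + i for i in range(n_instances)]
    summary = ComparisonSummary(force=force)

    for seed in seeds:
        graph = spec.generate(seed)
        if force == "increasing_flow":
            runs = {
                "with": (FlowSchedule.multiplicative(alpha), False),
                "without": (FlowSchedule.constant(), False),
            }
            objective = lambda path: len(path) - 1
        else:
            runs = {
                "with": (FlowSchedule.constant(), True),
                "without": (FlowSchedule.constant(), False),
            }
            objective = lambda path: path_leakage(graph, path)

        outcome = {}
        for label, (schedule, leak_on) in runs.items():
            _, rec = run_simulation(
                graph,
                rule,
                schedule,
                cfg,
                apply_leakage=leak_on,
                instance_id=f"{spec.family}-{seed}-{label}",
                seed=seed,
                record=False,
            )
            outcome[label] = rec
        summary.n_instances += 1
        if not (outcome["with"].converged and outcome["without"].converged):
            summary.n_excluded += 1
            continue
        summary.records.append(
            (
                seed,
                objective(outcome["with"].converged_path),
                objective(outcome["without"].converged_path),
            )
        )
    return summary


# ---------------------------------------------------------------------------
# counterexamples


@dataclass
class UnidirectionalDemo:
    """Two unidirectional runs differing only in the swap of the two s-incident
    initial pheromone levels, plus the paths they settle on."""

    baseline_path: tuple | None
    swapped_path: tuple | None
    baseline_mode: str  # 'converged' | 'dominant' | 'inconclusive'
    swapped_mode: str
    flipped: bool


def _settled_path(traj: Trajectory) -> tuple[tuple | None, str]:
    """Outcome path of a run: strict convergence, else a stable dominant path.

    With unidirectional flow and the linear rule the pheromone split at s is
    exactly invariant, so the strict (1 - tol) predicate can never fire even
    though one path permanently carries the majority of the flow; the dominant
    path (greedy max-pheromone path, stable with majority share over the final
    patience window) is then the meaningful outcome.
    """
    if traj.converged_path is not None:
        return traj.converged_path, "converged"
    graph, K = traj.graph, traj.config.patience
    if len(traj.pheromone) < K:
        return None, "inconclusive"
    tail = traj.pheromone[-K:]
    paths = {greedy_forward_path(graph, row) for row in tail}
    if len(paths) != 1 or None in paths:
        return None, "inconclusive"
    (path,) = paths
    from .model import path_min_normalized

    if min(path_min_normalized(graph, row, path) for row in tail) <= 0.5:
        return None, "inconclusive"
    return path, "dominant"


def counterexample_unidirectional(
    graph: FlowGraph,
    rule: DecisionRule,
    schedule: FlowSchedule,
    config: SimulationConfig | None = None,
) -> UnidirectionalDemo:
    """Demonstrate that unidirectional flow cannot guarantee the optimal path.

    Requires a two-parallel-paths graph and a schedule with zero backward
    injection.  Runs the dynamics twice -- once with the configured initial
    pheromone, once with the two s-incident levels swapped -- and reports the
    two settled paths; the demonstration succeeds when they differ, exhibiting
    an initialisation under which the dynamics misses the shortest /
    minimum-leakage path.
    """
    if schedule.backward(0) != 0.0:
        raise ValueError("unidirectional demo requires zero backward injection")
    cfg = config or SimulationConfig()

    s_edges = graph.out_edges(graph.source)
    if len(s_edges) != 2:
        raise ValueError("graph must be a two-parallel-paths instance")
    e1, e2 = s_edges

    def pmap(swap: bool):
        base = cfg.initial_pheromone
        if isinstance(base, (int, float)):
            levels = {e: float(base) for e in graph.edges}
        else:
            levels = {e: 0.0 for e in graph.edges}
            levels.update({tuple(k): float(v) for k, v in dict(base).items()})
        if swap:
            levels[e1], levels[e2] = levels[e2], levels[e1]
        return levels

    outcomes = []
    for swap in (False, True):
        cfg_run = SimulationConfig(
            delta=cfg.delta,
            horizon=cfg.horizon,
            tol=cfg.tol,
            patience=cfg.patience,
            rescale_period=cfg.rescale_period,
            initial_pheromone=pmap(swap),
            seed=cfg.seed,
        )
        traj = simulate(graph, rule, schedule, cfg_run, stop_on_convergence=True)
        outcomes.append(_settled_path(traj))

    (bp, bm), (sp, sm) = outcomes
    return UnidirectionalDemo(
        baseline_path=bp,
        swapped_path=sp,
        baseline_mode=bm,
        swapped_mode=sm,
        flipped=(bp is not None and sp is not None and bp != sp),
    )


@dataclass
class NonlinearDemo:
    """A constructed two-parallel-paths instance on which a nonlinear g-rule
    misses the target-optimal path."""

    graph: FlowGraph
    r: float
    g_r: float
    target: str
    schedule: FlowSchedule
    initial_pheromone: dict
    optimal_path: tuple
    settled_path: tuple | None
    converged: bool
    succeeded: bool  # dynamics did NOT settle on the optimal path
    alpha: float | None = None


def _find_r(g: Callable[[float], float], n_grid: int = 193, tol: float = 1e-6):
    """Grid-search an r in (0, 1/2) maximising |g(r) - r|."""
    xs = np.linspace(0.01, 0.49, n_grid)
    gaps = np.array([g(float(x)) - float(x) for x in xs])
    i = int(np.argmax(np.abs(gaps)))
    if abs(gaps[i]) < tol:
        return None, None
    return float(xs[i]), float(g(float(xs[i])))


def counterexample_nonlinear(
    g: Callable[[float], float],
    target: str = "leakage",
    config: SimulationConfig | None = None,
    g_name: str = "g-rule",
    alphas: Sequence[float] = (1.0005, 1.001, 1.002, 1.005, 1.01, 1.02, 1.05),
) -> NonlinearDemo:
    """Construct and run an instance where a nonlinear g-rule misses the target.

    Finds r with g(r) != r; biases the initial pheromone so that the
    non-optimal path P2 starts with normalised level 1 - r on the terminal
    edges.  For target='leakage' (constant flow) small leakages with
    l_P1 < l_P2 are set from the margin c = |g(r) - r|, so the leakage force
    points toward P1 while the nonlinearity keeps the flow on P2.  For
    target='length' (zero leakage) a multiplicative schedule is searched over
    a small alpha grid, reporting the factor used.
    """
    if target not in ("leakage", "length"):
        raise ValueError("target must be 'leakage' or 'length'")
    diag = validate_g_rule(g)
    if not diag:
        raise ValueError(f"invalid g-rule: {'; '.join(diag.messages)}")
    r, g_r = _find_r(g)
    if r is None:
        raise ValueError("rule numerically indistinguishable from linear")
    cfg = config or SimulationConfig()
    rule = GFamilyRule(g, name=g_name, validate=False)
    c = abs(g_r - r)
    favored_is_p2 = g_r < r  # sub-proportional g starves the low-pheromone side

    if target == "leakage":
        # equal-length paths isolate the leakage force; l_P1 < l_P2 both small
        # enough that the margin-based flow bounds persist
        l2 = c / (2.0 * (1.0 - r + c))
        l1 = l2 / 2.0
        graph = gen_parallel_paths(2, 2, [l1], [l2])
        schedule = FlowSchedule.constant()
        alphas_to_try = [None]
    else:
        graph = gen_parallel_paths(2, 3)  # P1 = the unique shortest path
        schedule = None
        alphas_to_try = list(alphas)

    # initial pheromone: normalised level r on P1's terminal-incident edges
    # (or on P2's, for the g(r) > r case where the equalising rule keeps P2's
    # share >= r forever and so prevents convergence to P1)
    p1_share = r if favored_is_p2 else 1.0 - r
    d_edge_p1, d_edge_p2 = graph.in_edges("d")
    init = {e: 1.0 for e in graph.edges}
    init[("s", "a1")] = p1_share
    init[("s", "b1")] = 1.0 - p1_share
    init[d_edge_p1] = p1_share
    init[d_edge_p2] = 1.0 - p1_share

    optimal = (
        oracle_min_leakage_path(graph) if target == "leakage" else oracle_shortest_path(graph)
    )

    best = None
    for a in alphas_to_try:
        sched = schedule if a is None else FlowSchedule.multiplicative(a)
        cfg_run = SimulationConfig(
            delta=cfg.delta,
            horizon=cfg.horizon,
            tol=cfg.tol,
            patience=cfg.patience,
            rescale_period=cfg.rescale_period,
            initial_pheromone=init,
            seed=cfg.seed,
        )
        traj = simulate(graph, rule, sched, cfg_run)
        settled, mode = _settled_path(traj)
        missed = settled != optimal  # non-convergence also misses the target
        demo = NonlinearDemo(
            graph=graph,
            r=r,
            g_r=g_r,
            target=target,
            schedule=sched,
            initial_pheromone=init,
            optimal_path=optimal,
            settled_path=settled,
            converged=(mode == "converged"),
            succeeded=missed,
            alpha=a,
        )
        if missed:
            return demo
        best = demo
    return best
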