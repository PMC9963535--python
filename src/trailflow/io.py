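"""File formats: TSV graphs, JSON/YAML run configs, CSV trajectories.

A graph on disk is a pair of TSV tables plus a small JSON sidecar naming the
terminals:

    PREFIX.edges.tsv     columns: u, v[, length]   (length >= 1, optional)
    PREFIX.vertices.tsv  columns: vertex, leakage
    PREFIX.meta.json     {"source": ..., "destination": ...}

Edges with a length column are expanded into unit-edge chains before
simulation.  Run configs are YAML (JSON being a subset) with the keys
{rule, schedule, delta, horizon, tol, patience, rescale_period, seed,
initial_pheromone}.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .model import FlowGraph, FlowSchedule, SimulationConfig, Trajectory, expand_weighted_edges
from .rules import rule_from_spec

__all__ = [
    "write_graph",
    "read_graph",
    "write_trajectory",
    "load_run_config",
    "export_graphml",
]


def _p(prefix: Path, suffix: str) -> Path:
    return prefix.parent / (prefix.name + suffix)


def _coerce(label):
    """Vertex labels round-trip as ints when they look like ints."""
    try:
        return int(label)
    except (TypeError, ValueError):
        return str(label)


def write_graph(graph: FlowGraph, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(graph.edges, columns=["u", "v"]).to_csv(
        _p(prefix, ".edges.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {"vertex": graph.vertices, "leakage": [graph.leakage[v] for v in graph.vertices]}
    ).to_csv(_p(prefix, ".vertices.tsv"), sep="\t", index=False)
    _p(prefix, ".meta.json").write_text(
        json.dumps({"source": graph.source, "destination": graph.destination})
    )


def read_graph(prefix: str | Path) -> FlowGraph:
    prefix = Path(prefix)
    edges_df = pd.read_csv(_p(prefix, ".edges.tsv"), sep="\t")
    verts_df = pd.read_csv(_p(prefix, ".vertices.tsv"), sep="\t")
    meta = json.loads(_p(prefix, ".meta.json").read_text())
    vertices = [_coerce(v) for v in verts_df["vertex"]]
    leakage = dict(zip(vertices, verts_df["leakage"].astype(float)))
    edges = [(_coerce(u), _coerce(v)) for u, v in zip(edges_df["u"], edges_df["v"])]
    graph = FlowGraph(
        vertices, edges, _coerce(meta["source"]), _coerce(meta["destination"]), leakage
    )
    if "length" in edges_df.columns:
        lengths = {
            e: int(l)
            for e, l in zip(edges, edges_df["length"])
            if pd.notna(l) and int(l) > 1
        }
        if lengths:
            graph = expand_weighted_edges(graph, lengths)
    return graph


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def load_run_config(path: str | Path):
    """Read a run config; returns (rule, schedule, SimulationConfig)."""
    raw = yaml.safe_load(Path(path).read_text())
    rule = rule_from_spec(raw.get("rule", "linear"))
    sched_raw = raw.get("schedule", {"kind": "constant"})
    schedule = FlowSchedule(
        kind=sched_raw.get("kind", "constant"),
        base_forward=float(sched_raw.get("base_forward", 1.0)),
        base_backward=float(sched_raw.get("base_backward", 1.0)),
        alpha=float(sched_raw.get("alpha", 0.0)),
    )
    init = raw.get("initial_pheromone", 1.0)
    if isinstance(init, dict):
        init = {tuple(_coerce(x) for x in k.split("->")): float(v) for k, v in init.items()}
    config = SimulationConfig(
        delta=float(raw.get("delta", 0.9)),
        horizon=int(raw.get("horizon", 5000)),
        tol=float(raw.get("tol", 1e-3)),
        patience=int(raw.get("patience", 25)),
        rescale_period=int(raw.get("rescale_period", 50)),
        initial_pheromone=init,
        seed=raw.get("seed"),
    )
    return rule, schedule, config


def export_graphml(graph: FlowGraph, path: str | Path) -> None:
    """GraphML export for interoperability with other graph tooling."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))
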