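import numpy as np
import pytest

from trailflow import (
    FlowGraph,
    FlowSchedule,
    LinearRule,
    SimulationConfig,
    gen_parallel_paths,
    simulate,
)


@pytest.fixture
def single_path_graph():
    """s -> v -> d with l_v = 0.5 (the hand-evaluated single-chain instance)."""
    return FlowGraph(["s", "v", "d"], [("s", "v"), ("v", "d")], "s", "d", {"v": 0.5})


@pytest.fixture
def symmetric_parallel():
    """Two parallel length-2 paths, zero leakage: exactly symmetric."""
    return gen_parallel_paths(2, 2)


@pytest.fixture
def leaky_parallel_graph():
    """Parallel (3, 3) with leakages 0.05/0.05 vs 0.2/0.2: P1 = a-path."""
    return gen_parallel_paths(3, 3, [0.05, 0.05], [0.2, 0.2])


def run_linear(graph, schedule=None, **cfg_kwargs):
    schedule = schedule or FlowSchedule.constant()
    return simulate(graph, LinearRule(), schedule, SimulationConfig(**cfg_kwargs))


@pytest.fixture
def rng():
    return np.random.default_rng(20230130)
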