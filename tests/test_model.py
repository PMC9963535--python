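"""Unit and property tests for the core flow/pheromone dynamics."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trailflow import (
    FlowGraph,
    FlowSchedule,
    LinearRule,
    PowerRule,
    SimulationConfig,
    advance_one_step,
    expand_weighted_edges,
    gen_gnp,
    gen_parallel_paths,
    initial_state,
    path_leakage,
    rescale_state,
    simulate,
)


class TestFlowGraphInvariants:
    def test_rejects_self_loops_duplicates_and_bad_leakage(self):
        with pytest.raises(ValueError):
            FlowGraph(["s", "d"], [("s", "s")], "s", "d")
        with pytest.raises(ValueError):
            FlowGraph(["s", "d"], [("s", "d"), ("s", "d")], "s", "d")
        with pytest.raises(ValueError):
            FlowGraph(["s", "v", "d"], [("s", "v"), ("v", "d")], "s", "d", {"v": 1.5})
        with pytest.raises(ValueError):  # terminals must not leak
            FlowGraph(["s", "v", "d"], [("s", "v"), ("v", "d")], "s", "d", {"s": 0.1})
        with pytest.raises(ValueError):
            FlowGraph(["s"], [], "s", "s")


class TestAdvanceOneStep:
    def test_hand_evaluated_single_chain_step(self, single_path_graph):
        """One full step on s->v->d with l_v=0.5, delta=0.5, injections 1/1."""
        g = single_path_graph
        state = initial_state(g, 1.0)
        new = advance_one_step(
            g, state, LinearRule(), FlowSchedule.constant(), SimulationConfig(delta=0.5)
        )
        assert new.fwd_vertex[g.index["v"]] == pytest.approx(0.5)
        assert new.bwd_vertex[g.index["v"]] == pytest.approx(0.5)
        assert new.pheromone_of(g, "s", "v") == pytest.approx(1.0)
        assert new.pheromone_of(g, "v", "d") == pytest.approx(1.0)

    def test_equal_pheromone_splits_symmetrically(self, symmetric_parallel):
        g = symmetric_parallel
        state = initial_state(g, 1.0)
        new = advance_one_step(g, state, LinearRule(), FlowSchedule.constant())
        for e in [("s", "a1"), ("s", "b1")]:
            assert new.fwd_edge[g.edge_index[e]] == pytest.approx(0.5)

    def test_zero_leakage_conserves_flow_each_step(self):
        """Total flow at t+1 = total at t + injections - deliveries, to 1e-12."""
        g = gen_gnp(12, 0.5, seed=3)
        state = initial_state(g, 1.0)
        sched = FlowSchedule.constant(1.0, 1.0)
        for _ in range(60):
            new = advance_one_step(g, state, LinearRule(), sched)
            before = state.fwd_vertex.sum() + state.bwd_vertex.sum()
            after = new.fwd_vertex.sum() + new.bwd_vertex.sum()
            injected = sched.forward(state.time) + sched.backward(state.time)
            assert after == pytest.approx(
                before + injected - new.delivered_forward - new.delivered_backward,
                abs=1e-12,
            )
            state = new

    def test_leakage_accounting_on_single_chain(self):
        """Delivered forward flow equals injected * (1 - l_P) on a lone path."""
        leaks = [0.1, 0.25, 0.3]
        vertices = ["s", "v1", "v2", "v3", "d"]
        edges = list(zip(vertices[:-1], vertices[1:]))
        g = FlowGraph(vertices, edges, "s", "d", dict(zip(["v1", "v2", "v3"], leaks)))
        # single pulse: inject once, then watch it arrive len(path) steps later
        state = initial_state(g, 1.0)
        sched = FlowSchedule.constant(1.0, 0.0)  # forward pulse train only
        deliveries = []
        for _ in range(len(edges)):
            state = advance_one_step(g, state, LinearRule(), sched)
            deliveries.append(state.delivered_forward)
        expected = math.prod(1 - l for l in leaks)  # = 1 - l_P per pulse
        assert deliveries[-1] == pytest.approx(expected, abs=1e-12)
        assert path_leakage(g, vertices) == pytest.approx(1 - expected)

    def test_uniform_fallback_on_zero_pheromone(self, caplog):
        g = gen_parallel_paths(2, 2)
        state = initial_state(g, {e: 0.0 for e in g.edges})
        with caplog.at_level(logging.WARNING, logger="trailflow.model"):
            new = advance_one_step(g, state, LinearRule(), FlowSchedule.constant())
        assert new.fwd_edge[g.edge_index[("s", "a1")]] == pytest.approx(0.5)
        assert "zero total pheromone" in caplog.text

    def test_nan_pheromone_is_a_hard_error(self, symmetric_parallel):
        state = initial_state(symmetric_parallel, 1.0)
        state.pheromone[0] = np.nan
        with pytest.raises(FloatingPointError):
            advance_one_step(
                symmetric_parallel, state, LinearRule(), FlowSchedule.constant()
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        exponent=st.sampled_from([1.0, 1.1, 2.0]),
    )
    def test_nonnegativity_preserved(self, seed, exponent):
        rng = np.random.default_rng(seed)
        g = gen_parallel_paths(2, 3, [rng.uniform(0, 0.5)], [rng.uniform(0, 0.5)] * 2)
        state = initial_state(g, dict(zip(g.edges, rng.uniform(0, 2, g.m))))
        rule = PowerRule(exponent)
        for _ in range(10):
            state = advance_one_step(g, state, rule, FlowSchedule.constant())
            assert np.all(state.pheromone >= 0)
            assert np.all(state.fwd_vertex >= 0) and np.all(state.bwd_vertex >= 0)


class TestScaleInvariance:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        c=st.floats(1e-6, 1e6),
        exponent=st.sampled_from([1.0, 1.1, 2.0]),
        seed=st.integers(0, 1000),
    )
    def test_joint_rescaling_leaves_fractions_unchanged(self, c, exponent, seed):
        """Scaling pheromone, flows and injections by c > 0 preserves every
        flow fraction for the ratio-based rules."""
        rng = np.random.default_rng(seed)
        g = gen_parallel_paths(2, 3)
        p0 = dict(zip(g.edges, rng.uniform(0.1, 2.0, g.m)))
        rule = PowerRule(exponent)

        s1 = initial_state(g, p0)
        s2 = rescale_state(initial_state(g, p0), c)
        sched1 = FlowSchedule.constant(1.0, 1.0)
        for _ in range(8):
            s1 = advance_one_step(g, s1, rule, sched1)
            s2 = advance_one_step(g, s2, rule, sched1)  # injections auto-scaled
            with np.errstate(invalid="ignore"):
                f1 = s1.fwd_edge / np.where(s1.fwd_edge.sum() > 0, s1.fwd_edge.sum(), 1)
                f2 = s2.fwd_edge / np.where(s2.fwd_edge.sum() > 0, s2.fwd_edge.sum(), 1)
            np.testing.assert_allclose(f1, f2, rtol=1e-9, atol=1e-12)


class TestRescaleState:
    def test_factor_one_is_identity(self, symmetric_parallel):
        state = initial_state(symmetric_parallel, 1.0)
        assert rescale_state(state, 1.0) is state

    def test_nonpositive_factor_rejected(self, symmetric_parallel):
        state = initial_state(symmetric_parallel, 1.0)
        with pytest.raises(ValueError):
            rescale_state(state, 0.0)
        with pytest.raises(ValueError):
            rescale_state(state, -2.0)

    def test_rescale_by_inverse_max_normalises_peak(self, leaky_parallel_graph):
        traj = simulate(
            leaky_parallel_graph,
            LinearRule(),
            FlowSchedule.constant(),
            SimulationConfig(horizon=40),
            stop_on_convergence=False,
        )
        state = traj.final_state
        scaled = rescale_state(state, 1.0 / state.pheromone.max())
        assert scaled.pheromone.max() == pytest.approx(1.0)

    def test_periodic_rescaling_reproduces_normalized_series(self):
        """A multiplicative run with and without periodic rescaling yields
        identical normalised pheromone series within 1e-9."""
        g = gen_parallel_paths(2, 5)
        kw = dict(horizon=400, initial_pheromone=1.0)
        a = simulate(g, LinearRule(), FlowSchedule.multiplicative(1.5),
                     SimulationConfig(**kw, rescale_period=50), stop_on_convergence=False)
        b = simulate(g, LinearRule(), FlowSchedule.multiplicative(1.5),
                     SimulationConfig(**kw, rescale_period=10**6), stop_on_convergence=False)
        for u, v in g.edges:
            np.testing.assert_allclose(
                a.normalized_forward_series(u, v),
                b.normalized_forward_series(u, v),
                atol=1e-9,
            )
        assert a.scale_offsets[-1] < 0 < math.exp(b.scale_offsets[-1])


class TestPathLeakage:
    def test_matches_definition_product(self):
        g = gen_parallel_paths(3, 2, [0.1, 0.2], [0.0])
        assert path_leakage(g, ("s", "a1", "a2", "d")) == pytest.approx(0.28)
        assert path_leakage(g, ("s", "b1", "d")) == pytest.approx(0.0)

    def test_absorbing_internal_vertex(self):
        g = gen_parallel_paths(2, 2, [1.0], [0.0])
        assert path_leakage(g, ("s", "a1", "d")) == pytest.approx(1.0)

    def test_invalid_sequences_rejected(self):
        g = gen_parallel_paths(2, 2)
        for bad in [("s", "b1"), ("a1", "d"), ("s", "a1", "b1", "d"), ("s", "d")]:
            with pytest.raises(ValueError):
                path_leakage(g, bad)


class TestExpandWeightedEdges:
    def test_length_three_edge_becomes_chain(self):
        g = FlowGraph(["s", "d"], [("s", "d")], "s", "d")
        out = expand_weighted_edges(g, {("s", "d"): 3})
        assert out.n == 4 and out.m == 3
        new = [v for v in out.vertices if v not in ("s", "d")]
        assert all(out.leakage[v] == 0.0 for v in new)
        assert out.is_valid_path((out.source, *new, out.destination))

    def test_unit_lengths_leave_graph_unchanged(self, leaky_parallel_graph):
        out = expand_weighted_edges(leaky_parallel_graph, {e: 1 for e in leaky_parallel_graph.edges})
        assert out.edges == leaky_parallel_graph.edges
        assert out.vertices == leaky_parallel_graph.vertices

    def test_two_parallel_length2_edges_counted(self):
        g = gen_parallel_paths(1, 2)  # s->d direct plus s->b1->d
        out = expand_weighted_edges(g, {("s", "d"): 2, ("s", "b1"): 2})
        assert out.m == 5 and out.n == 5

    def test_bad_lengths_rejected(self):
        g = FlowGraph(["s", "d"], [("s", "d")], "s", "d")
        with pytest.raises(ValueError):
            expand_weighted_edges(g, {("s", "d"): 0})
        with pytest.raises(ValueError):
            expand_weighted_edges(g, {("s", "d"): 2.5})


class TestFlowSchedule:
    def test_kind_constraints(self):
        with pytest.raises(ValueError):
            FlowSchedule.multiplicative(1.0)  # needs alpha > 1
        with pytest.raises(ValueError):
            FlowSchedule.additive(0.0)  # needs alpha > 0
        with pytest.raises(ValueError):
            FlowSchedule("constant", 0.0, 0.0)

    def test_profiles(self):
        assert FlowSchedule.constant(2.0).forward(17) == 2.0
        assert FlowSchedule.multiplicative(1.5, 2.0).forward(3) == pytest.approx(2 * 1.5**3)
        assert FlowSchedule.additive(0.5, 1.0).forward(4) == pytest.approx(3.0)

    def test_simulation_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(delta=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(tol=0.7)
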