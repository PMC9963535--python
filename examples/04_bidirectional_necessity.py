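"""Why the flow must run in both directions.

With forward flow only, the pheromone on the two edges leaving s is refreshed
only by that same forward flow, so the split at s can never learn anything
about path lengths or losses downstream: whichever edge starts with more
pheromone keeps its majority forever.  Swapping the two initial values swaps
the outcome.  Restoring backward flow breaks this symmetry and the shortest
path wins from either initialisation.
"""

from trailflow import (
    FlowSchedule,
    LinearRule,
    SimulationConfig,
    counterexample_unidirectional,
    gen_parallel_paths,
    simulate,
)

graph = gen_parallel_paths(2, 4)
init = {e: 1.0 for e in graph.edges}
init[("s", "b1")] = 10.0  # the long path starts with 10x the pheromone

demo = counterexample_unidirectional(
    graph,
    LinearRule(),
    FlowSchedule("multiplicative", base_forward=1.0, base_backward=0.0, alpha=1.1),
    SimulationConfig(initial_pheromone=init),
)
print("unidirectional, biased init  ->", demo.baseline_path, f"({demo.baseline_mode})")
print("unidirectional, swapped init ->", demo.swapped_path, f"({demo.swapped_mode})")
print("outcome flipped by the swap: ", demo.flipped)

traj = simulate(
    graph,
    LinearRule(),
    FlowSchedule.multiplicative(1.1),
    SimulationConfig(initial_pheromone=init),
)
print("bidirectional, same biased init ->", traj.converged_path)
# 'dominant' marks a stable majority split rather than full convergence: the
# unidirectional linear dynamics freezes the initial 10:1 split exactly.
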