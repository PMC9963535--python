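"""Increasing flow + linear rule converges to the shortest path.

With no leakage, a steady flow cannot distinguish a 2-edge route from a
5-edge route.  But when the injection rate grows (here 5% per step), the flow
arriving over the shorter route is always "younger" and therefore larger, so
its edges accumulate relatively more pheromone and the short route wins.
"""

from trailflow import (
    FlowSchedule,
    LinearRule,
    SimulationConfig,
    gen_parallel_paths,
    oracle_shortest_path,
    simulate,
)

graph = gen_parallel_paths(2, 5)

constant = simulate(graph, LinearRule(), FlowSchedule.constant(), SimulationConfig())
print("constant injection  -> converged path:", constant.converged_path)

for alpha in (1.05, 1.5):
    traj = simulate(
        graph, LinearRule(), FlowSchedule.multiplicative(alpha), SimulationConfig()
    )
    print(
        f"multiplicative x{alpha} -> converged path: {traj.converged_path} "
        f"(step {traj.convergence_time})"
    )

print("shortest-path oracle:", oracle_shortest_path(graph))
# Under constant injection the symmetric start stays split (None = no single
# path ever dominates); with increasing injection the 2-edge path wins, and
# faster growth converges sooner.
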