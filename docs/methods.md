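# Methods

## The dynamical system

The state at integer time *t* is a non-negative pheromone level per edge and
a non-negative forward/backward flow per vertex.  One step applies, in order:

1. **Injection.**  `FlowSchedule` adds new forward flow at *s* and backward
   flow at *d*.  Injection happens at the start of the step, before edges are
   chosen, so flow injected at *t* traverses its first edge during step *t*.
2. **Edge distribution.**  Each vertex's forward flow divides over its
   outgoing edges (backward flow over incoming edges) by the decision rule
   applied to those edges' pheromone levels.
3. **Leakage.**  Flow arriving at vertex *v* is multiplied by (1 − l_v).
   Terminals always have l = 0.
4. **Pheromone update.**  p(t+1) = δ·(p(t) + f→(t) + f←(t)), where the edge
   flows are the ones that moved in this step.  Pheromone is directionless.
5. **Absorption.**  Forward flow reaching *d* and backward flow reaching *s*
   is recorded as delivered and removed: ants reaching a terminal continue
   into other parts of the colony's network rather than turning around, and
   backward injection at *d* is deliberately independent of the forward flow
   delivered there.

The dynamics is deterministic; all randomness in the package lives in the
graph generators and in initial-condition draws, and is always seeded.

Degenerate cases: a vertex holding flow whose candidate edges all have zero
pheromone splits uniformly (logged once per run) — this cannot arise from a
positive initial pheromone, since the decay is multiplicative, but
file-supplied states may contain it.  Flow on a vertex with no outgoing
edges (possible only in user-supplied cyclic graphs; generated graphs are
pruned DAGs) is dropped and logged.  Negative or non-finite state values are
hard errors.

## Decision rules

* **Linear**: fractions p_i / Σp_j.  The unique member of the family below
  with guaranteed convergence to the minimum-leakage and shortest paths.
* **Power (k)**: fractions p_i^k / Σp_j^k; k = 2 is the quadratic rule, and
  k = 1.1 a near-linear rule.  Levels are divided by their maximum before
  exponentiation so that astronomically large pheromone cannot overflow.
* **g-family**: for degree ≤ 2 only, a monotone g: [0, ½] → [0, 1] with
  g(0) = 0 and g(½) = ½ receives the smaller *normalised* pheromone x and
  returns that edge's fraction.  g(x) = x is the linear rule; the two-edge
  power rule corresponds to g(x) = x^k / (x^k + (1−x)^k).  Validation checks
  the endpoint identities to 1e−12 and monotonicity on a 1001-point grid
  (sampling, not proof).  Vertices of degree ≥ 3 under a nonlinear rule use
  the power rule; g-rules raise an error there, since the family is defined
  only for degree ≤ 2.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| δ (decay) | 0.9 | per-step multiplicative pheromone decay; any δ ∈ (0,1) preserves the convergence hypotheses, 0.9 keeps a useful memory length (~10 steps) without freezing the dynamics |
| initial pheromone | 1.0 per edge | satisfies the positivity hypothesis of both convergence results symmetrically; configurable per edge |
| injection bases | 1.0 / 1.0 | units are arbitrary: the linear/power rules are ratio-based, so jointly scaling flows and pheromone changes nothing (tested) |
| horizon | 5000 | default cap for single runs |
| tol | 1e−3 | convergence: every edge of a path holds normalised pheromone ≥ 1 − tol |
| patience K | 25 | consecutive steps the predicate must hold |
| rescale_period | 50 | steps between renormalisations under multiplicative schedules |

## Finite-time convergence predicate

The convergence claims are asymptotic.  Operationally a run *converges* when
the path obtained by following the max-pheromone outgoing edge from *s*
keeps forward-normalised pheromone ≥ 1 − tol on every edge for K consecutive
steps.  Because tol < ½, a path satisfying the bound is unique and coincides
with the greedy path, so the detector is equivalent to scanning all paths
(tested against that brute force).  Runs that do not satisfy the predicate
within the horizon are reported as non-converged, and batch analyses exclude
and count them.  Convergence *times* are implementation-defined quantities:
they depend on tol, K, δ and the initial state, and are not comparable
across conventions.

Two situations legitimately never converge under this predicate:

* **Exact ties.**  Equally optimal alternatives (two equal-length,
  equal-leakage routes; the many equal shortest paths of an n×n grid with no
  leakage) reach a frozen split: under the linear rule the pheromone ratio
  between tied routes is exactly invariant.  Sweep analyses therefore score a
  converged run by its *objective value* (path length, or compounded
  path leakage) rather than by vertex-sequence identity.
* **Additive schedules.**  With injection base + αt the *relative* flow
  advantage of the shorter path decays like 1/t, so the pheromone ratio grows
  only polynomially with a small exponent.  Additive demonstrations
  therefore use a looser dominance threshold (tol = 0.2) and geometries with
  a length gap ≥ 2; multiplicative schedules converge exponentially and use
  the strict default.

## Numerical stabilisation

Multiplicative injection α^t overflows double precision near t ≈ 700/log₁₀α.
Every `rescale_period` steps the whole state is multiplied by 1/max(p) and
the log of the cumulative factor is stored in `scale_offset`; future
injections are multiplied by exp(scale_offset), evaluated in log space.
Because all built-in rules are ratio-based, normalised pheromone and every
flow fraction are invariant — a paired rescaled/unrescaled run agrees to
≤ 1e−9 (tested at machine precision).  A losing path's rescaled pheromone can
underflow to exact zero; the resulting infinite pheromone ratio is a legal
terminal state of convergence, not an error.

## Potential function

For a two-parallel-paths graph with designated target path P1,
r_ss1(t) = p_ss1/p_ss2 and r_d1d(t) = p_d1d/p_d2d are the P1:P2 ratios at the
edge pairs leaving *s* and entering *d*, and

    r_min(t) = min of the last L values of both series,  L = max(len_P1, len_P2).

Under either convergence regime r_min never decreases and strictly increases
across every L-step window; the monotonicity check uses a relative tolerance
(1e−9) because the ratios span hundreds of decades, and treats +inf as a
terminal maximum.

## Oracles

* Shortest path: minimum edge count, ties broken by fewer vertices then by
  lexicographically smallest label sequence (labels compare natively when
  mutually comparable, else as strings).
* Minimum-leakage path: Dijkstra on vertex entry costs −log(1 − l_v)
  (l_v = 1 is unusable), same tie-breaking; verified against exhaustive path
  enumeration on small random graphs.
* The leakage-vs-vertex-count check verifies that when all log(1 − l_v)
  values lie within a (1 + ε) factor, the minimum-leakage path has at most
  (1 + ε) times the vertices of the minimum-vertex path.

## Generators (the study conditions)

* `gnp`: one Bernoulli(p) draw per unordered pair {i, j}, edge oriented
  i → j for i < j (a DAG), s = 1, d = n; resampled (budget 100) until an
  s→d path exists, then pruned to vertices/edges on s→d paths.  The locality
  variant masks pairs with |i − j| > k *after* drawing, so a vacuous
  constraint reproduces the unconstrained graph at the same seed.
* `grid`: n×n lattice directed right/down, s and d at opposite corners.
* `parallel_paths`: the two-route gadget of the analytic results.
* Leakage: constant, or i.i.d. uniform on [0, l_max] (default experiments
  use l_max = 0.3), terminals always 0.
* Weighted edges: an integer length-k edge expands into k unit edges through
  k − 1 fresh zero-leakage vertices.

Random-graph sweeps draw initial pheromone uniform on [0.5, 1.5] per edge:
a perfectly symmetric start on a symmetric graph preserves its symmetry
forever under the deterministic dynamics, which would make grid instances
trivially unconvergeable; any positive initial pheromone satisfies the
convergence hypotheses.  The paired-comparison protocol (quadratic rule,
50 local random graphs, n = 20, p = 0.3, k = 5) keeps initial pheromone at
exactly 1.

These generators emulate the *structure* of vegetation networks (locality,
lattices) but none of their geometry, growth or rupture; real trail networks
also face link failures and multiple terminals, which are out of scope here.
Passing sweeps show the dynamics' optimisation behaviour on these families,
not performance on field-measured canopy graphs.

## Counterexample constructions

* **Unidirectional flow.**  With backward injection zero and the linear
  rule, the pheromone ratio at the two s-edges is exactly invariant, so the
  initial split persists; a 10:1 bias toward the long path keeps ~91% of the
  flow there, and swapping the two initial values swaps the outcome.  Since
  the strict predicate cannot fire on a frozen split, the demonstration
  reports the *stable dominant path* (greedy path, stable with majority
  share over the final K steps), flagged `dominant`.
* **Nonlinear rules.**  Grid-search r ∈ (0.01, 0.49) maximising |g(r) − r|
  (error below 1e−6 means the rule is numerically indistinguishable from
  linear).  For the leakage target: equal-length routes, initial normalised
  pheromone r on P1's terminal edges, and leakages l_P2 = c/(2(1 − r + c)),
  l_P1 = l_P2/2 with c = |g(r) − r| — small enough that the sub-proportional
  rule keeps starving P1 even though P1 leaks less.  For the length target:
  routes of lengths 2 and 3, zero leakage, and the multiplicative factor
  found by ascending grid search over {1.0005 … 1.05}, reported in the
  record; the g(r) > r (equalising) case is handled symmetrically, where
  success is non-convergence to the optimum.

## Problem sizes

Defaults were chosen so a single run completes in well under a second and
full sweeps in minutes: sweeps use 50 instances per family with n ≤ 30
(G(n,p) families) and n ≤ 6 (grids), horizons of 12000 (constant flow) and
6000 (increasing flow); the paired-comparison protocol uses 50 instances at
horizon 5000.  All are configuration parameters, not limits of the
implementation.

## Known limitations

* Two terminals only; no multi-terminal (Steiner-style) networks, no
  multi-commodity flow, and no agent-level stochastic simulation — the model
  is a deterministic flow.
* Convergence guarantees are demonstrated, not proved, outside the
  two-parallel-paths gadget; on general graphs they are an (extensively
  simulated) conjecture.
* The reachability-based pruning guarantees the "every edge on an s→d path"
  invariant only on DAGs; on user-supplied cyclic graphs an edge may survive
  that lies only on non-simple s→d walks.
* Grid instances without leakage have no unique optimum and therefore no
  single-path convergence; this is a property of the dynamics, not a bug.
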