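# Methods

This note documents the models implemented in `logictrain`, their
assumptions, the parameters that matter, the synthetic study used for
validation, and the numerical and design choices made where the design was
genuinely open.

## Model and objective

A prior knowledge network (PKN) is a signed directed graph of protein
interactions. Training selects a sub-hypergraph of the *scaffold* — the
compressed and expanded PKN — that best explains perturbation data under a
logic semantics. A candidate model is a bitstring P ∈ {0,1}^r over the
scaffold gates; its score is

θ(P) = θ_f(P) + α·θ_s(P),

where θ_f is the mean squared deviation between simulated and measured
values over all matched (condition, readout, time) points (missing data are
excluded from both the sum and the divisor n_g), and
θ_s = (1/v_es)·Σ_e v_e P_e charges each selected gate its input count v_e,
normalised by the scaffold total v_es. α (dimensionless, default shown in
examples as 1e-3–0.1) trades fit against size; it has no universal default
and should be set small relative to the expected θ_f scale so it acts as a
tie-break towards parsimony. Because data are normalised to [0,1] rather
than discretised, an intermediate measurement (0.5) penalises either
Boolean prediction equally (0.25) — uncertain points weigh less.
Predictions flagged UNRESOLVED (oscillating nodes, below) contribute
`na_penalty` (default 1.0, i.e. a maximal mismatch) per matched point.

## Preprocessing

*Pruning* removes nodes that are not reachable from any cue or cannot reach
any readout; nodes that are stimulated, inhibited or measured ("designated")
are never removed. *Compression* iteratively removes an undesignated node
with exactly one incoming or exactly one outgoing edge, rewiring each
(in, out) pair into a direct edge with the product of the signs. A removal
is skipped when it would (i) create a self-loop, (ii) contradict an existing
edge (same endpoints, opposite sign), or (iii) route a multi-input node
through a negative output — case (iii) would distribute the negation over
the implicit OR (De Morgan) and change the input–output logic, which a
brute-force property test confirms. These guards are what preserve feedback
intermediates. *Expansion* creates, per target node, one single-input gate
per signed edge plus one AND gate per combination of distinct inputs up to
`max_and_arity` (default 2 — pairwise gates cover the canonical
two-regulator motifs while keeping the search space 2^r tractable; higher
arities only add gates). OR is encoded by co-selection, so the bitstring
length equals the hyperedge count and θ_s's v_e is exactly the per-gate
input count. Gate order is lexicographic (output, arity, inputs) so saved
bitstrings are portable.

## Simulation engines

**Boolean steady state.** Synchronous updates from the cue pattern
(stimulated nodes at their treatment value, everything else 0); inhibited
nodes are clamped to 0 and stimuli to their treatment value at every step
(a drug is modelled as a full block; partial inhibition is out of scope for
the Boolean modes). A node with no selected incoming gate holds its initial
value, which makes the empty model well defined. Iteration stops at a
fixpoint or after `max_iter = ceil(1.2·|nodes|)` steps; on non-convergence
the engine probes a further window of steps and flags every node that still
changes as UNRESOLVED (a single-step check would miss half the nodes of a
period-4 cycle). Only the chosen pseudo-steady-state time enters θ_f;
the baseline time is used for normalisation only.

**Two pseudo-steady states.** Step 1 trains against τ1 as above. Step 2
searches only gates absent from the τ1 optimum (the single best model, not
the family), scores against τ2, and simulates each condition from its τ1
steady state with every node that receives a selected τ2 gate locked to
that gate's output evaluated at the τ1 state (OR across several τ2 gates
into one node); the rest of the network relaxes through the combined model.
Locking is what lets a slow negative feedback hold its target OFF instead
of oscillating. The τ2 size penalty covers the added gates only. The τ2
result depends on which τ1 optimum is chosen; this is inherent to the
two-pass design and exposed, not resolved.

**Discrete time.** The same synchronous update, but the whole trajectory is
kept and compared to every measured time: the model value at data time t is
the state at step round(t/δ) (Boolean states are step functions, so
nearest-step sampling, no interpolation; steps beyond the horizon hold the
last state; the baseline time is scored at step 0). The single time-scale
factor δ is trained jointly with the bitstring as one extra chromosome gene
indexing a log-spaced grid (default 20 points spanning max_time/100 to
max_time), encoded in binary so the binary GA is reused unchanged.

**Constrained fuzzy logic.** States are continuous in [0,1]; each selected
gate input passes through a transfer function from a discrete menu of
normalized Hill curves f(x) = g·x^n(1+K^n)/(x^n+K^n); AND = min over
transferred literals, OR = max over co-selected gates, negative literals
transfer the complement f(1−x). With unit gain, f(0)=0 and f(1)=1, so the
fuzzy model agrees with the Boolean one whenever states sit at 0/1 — and on
binary cues the synchronous fixpoints of unit-gain models *are* Boolean.
Sub-unit gains are therefore essential: they are the only mechanism by
which a steady-state fuzzy model can express sub-maximal activation, and
the menu includes them (defaults: n ∈ {2,4}, K ∈ {0.2,0.3,0.4,0.55,0.7,
0.85,1}, g ∈ {0.5,1}, plus the identity; all configurable). Training reuses
the binary GA with one menu index per gate input; the Boolean optimum
(encoded with unit-gain transfers) is seeded into the initial population so
the fuzzy fit can never be worse than the Boolean one. A refinement step
(Nelder–Mead over the selected (n, K, g), kept only if it does not worsen
θ) and a reduction step (greedily drop gates / demote transfers to the
identity while θ worsens by at most `reduction_threshold`, default 1e-4,
ties accepted) follow. Fixed-point tolerance 1e-4; non-convergent nodes are
flagged UNRESOLVED as in the Boolean engine.

**Logic-derived ODEs.** Each non-cue species follows
ẋ_i = (B̄_i(x) − x_i)/τ_i with a first-order decay and time constant τ_i in
data-time units. B̄_i composes the selected gates as a probabilistic OR
(1 − Π(1 − gate)) of products of transferred literals (normalized Hill
h(x), or 1−h(x) for inhibition). This composition is exactly Boolean at
vertex inputs for every gate and sign pattern (tested exhaustively to three
inputs) and matches the two canonical cases OR: x1+x2−x1x2 and AND: x1·x2;
it differs from a full multilinear interpolation of the node's truth table
only when co-selected gates share inputs, a trade made to keep one (n, K)
pair per gate input. Since B̄ ∈ [0,1], the flow cannot leave the unit cube.
Stimuli are held at their treatment value and inhibited nodes at 0 for the
whole trajectory. Integration uses stiff-capable `solve_ivp` (LSODA,
rtol 1e-8/atol 1e-10 for simulation, 1e-5/1e-7 during fitting, where all
conditions are also stacked into one system for speed). Fitting adjusts
(n, K) per gate input and τ per driven node within bounds n ∈ [1,10],
K ∈ [0.01,1], τ ∈ [0.01, 10·max time], searching K and τ in log space.
Two modes: a stochastic global optimiser (differential evolution with
polish; any bound-constrained minimiser can be plugged in via
`optimizer(fun, bounds, seed)`) for small parameter sets, and a
bound-constrained least-squares mode from neutral initial values for larger
fixed-topology fits, where the residual landscape is smooth.

## Genetic algorithm

Binary chromosomes, tournament selection (size 2), uniform crossover
(rate 0.8), per-bit mutation 0.5/r, elitism 2, population 50, up to 500
generations with a 100-generation stall criterion (all configurable; the
validation runs use smaller budgets stated in the tests). The empty and
full chromosomes are always injected into generation 0, so the reported
optimum is bounded by both baseline models. Every evaluated chromosome is
cached and archived exactly once; the family is every archived model with
θ ≤ (1+tolerance)·θ_best (relative tolerance, because the natural scale of
an acceptable score is set by the experimental error through θ_best
itself; the family is collected from all evaluated models, not the final
population). Identical seeds give bit-identical results. An exhaustive
enumerator (guarded at 20 free bits) serves as the oracle in tests.

## Data normalisation

For each condition/readout with baseline x0 (the value at the smallest
time) and M the readout's maximum raw value anywhere: fc = max(0,(x−x0)/x0)
("increase" mode; "decrease" mirrors it, "two-sided" uses |x−x0|/x0), then
H(fc) = fc^k/(ec50^k + fc^k) with defaults k = 2, ec50 = 0.5 (in
fold-change units), multiplied by the background penalty min(1, x/M). Raw
values below `background_threshold` map to 0; a zero or missing baseline
leaves the cell missing rather than dividing by zero. The Hill-on-fold-
change with a linear capped saturation is the simplest scheme consistent
with the verbal recipe the normalisation follows; all parameters are
configurable, and readouts expected to fall below baseline are handled by
the mode flag rather than a hard-coded convention.

## The synthetic toy study

`logictrain.fixtures` generates the validation study: a 13-species,
17-edge PKN of the canonical EGF and TNFa pathways and a simulated MIDAS
dataset under the four cue combinations (none, EGF, TNFa, both), sampled at
t = 0…60 min (12 points) with truncated Gaussian noise (sd 0.03). Data are
produced by the package's own logic-ODE engine from a documented generating
sub-model, starting from the unstimulated equilibrium. Three behaviours are
planted, each switchable in `ToySpec`:

- **Transient ERK** — a slowly accumulating ERK-induced phosphatase (mkp,
  τ = 12 min) shuts the fast cascade off: ERK peaks ≈ 0.7 around t = 3–6
  and settles ≈ 0.17. The classic ERK ⊣ SOS-1 feedback annotation is also
  in the PKN; after compression it becomes the EGF∧¬ERK candidate gate the
  two-time-scale trainer selects.
- **nfkb oscillation** — a steep three-step loop nfkb → ikbm → ikb ⊣ nfkb
  (n = 10, K = 0.5, τ = 5 min) produces a sustained ≈ 15-min limit cycle.
  The PKN also carries the direct negative nfkb ⊣ ikb annotation;
  contradictory annotation pairs of this kind are common in real PKNs, and
  here the contradiction guard is what keeps ikbm out of compression.
- **Partial p38** — a p38-induced phosphatase (dusp, τ = 8 min) brakes the
  p38 branch to an interior equilibrium; the level is highest (≈ 0.5)
  under co-stimulation because both pathways feed p38.

The kinetic constants (`fixtures._TAU`, `fixtures._TF`) were chosen once to
place the transient peak and the oscillation period inside the sampling
window and are not revisited. What the generator does *not* emulate:
biological replicate structure, heteroscedastic measurement error,
antibody cross-reactivity, unknown missing interactions (the generating
model is inside the scaffold by construction), and partial drug inhibition.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative discrimination between formalisms under realistic dynamics —
not robustness to model misspecification on real screens.

The five-formalism contrast validated on this study: the single
steady-state Boolean fit recovers the activating paths but none of the
feedback gates; the two-time-scale fit selects the EGF∧¬ERK gate with
family frequency 1.0; the discrete-time fit selects an nfkb negative-loop
gate and oscillates; the fuzzy fit cuts θ_f well below the Boolean optimum
by fitting the partial p38 level through sub-unit gains; the ODE fit,
initialised at neutral parameter values (n = 3, K = 0.5, τ = 5) with the
generating topology fixed, reproduces all three behaviours.

## Numerical choices and degenerate inputs

- Duplicate condition/time cells in MIDAS are an error by default
  (averaging behind `merge_duplicates`) — silent averaging hides data
  problems. Inhibitor columns are recognised by the `i` suffix with an
  explicit override set, since MIDAS dialects vary.
- Fully masked GA searches return the single admissible model with a
  warning; empty scaffolds (v_es = 0) and empty comparable-data sets
  (n_g = 0) raise.
- Score ties in the family bound use a 1e-12 absolute slack to absorb
  floating-point noise; GA improvement requires more than 1e-15.
- ODE solver failures during fitting (pathological parameter corners)
  score 1e6 instead of aborting the search; trajectories are clipped to
  [0,1] to absorb solver tolerance overshoot.
- Isolated nodes cannot be represented in SIF rows and are dropped on
  round-trip by design; node-status attribute files write `unknown` for
  unmapped nodes.

## Known limitations

- Boolean inhibition is all-or-none; dose–response cues are only supported
  through the continuous formalisms' treatment values.
- The discrete-time formalism shares one δ across all reactions, so it can
  fit a sustained oscillation but not a single transient pulse whose decay
  is slower than its rise (synchronous Boolean dynamics are eventually
  periodic).
- The τ2 search starts from one τ1 model; model-family uncertainty does not
  propagate between the passes.
- Structure search in ODE mode is out of scope: topology comes from one of
  the discrete trainers, parameters from the ODE fit.
- The published liver-cancer benchmark is supported through
  `logictrain.benchmark.load_benchmark`, but its dataset is not
  redistributed with the package; the corresponding check fails until the
  user supplies the files under `data/hepg2/`.
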