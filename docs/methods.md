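# Methods

## Propagation model and influence

The package models a signaling network as a signed directed graph and
propagates activity linearly: `x(t+1) = α W x(t) + β b`. `W` is the
degree-normalized link-weight matrix (target rows, source columns), `b` the
basal activities, and `α, β` mix incoming signal flow against basal drive.
The model is deliberately parameter-free beyond `(α, β)`: it trades
mechanistic fidelity for applicability to networks where only topology is
curated.

Influence is the steady-state sensitivity `S_ij = dx_i/db_j`. Because the
model is linear, `S` is the walk series `β Σ_k (αW)^k`: every directed walk
from *j* to *i* contributes `β α^len Π(weights)`, so path length is
discounted geometrically by `α` and path sign is the product of link signs.
The series converges iff `ρ(αW) < 1`, in which case
`S* = β (I − αW)⁻¹` and the steady state satisfies `x* = S* b`.

Three computation routes are implemented and cross-checked:

1. **exact** — dense linear solve of `(I − αW) S = βI`. Guarded by an
   eigenvalue-based spectral-radius check; on divergence it raises with
   instructions to fall back to the bounded iteration.
2. **iterative** — `S ← αW·S + βI` from `S₀ = βI`. The recurrence is chosen
   so that the t-th iterate equals the order-t partial sum of the walk
   series exactly; on an acyclic network the iteration is therefore *exact*
   once the longest path is exhausted. Stopping rule:
   `‖S(t+1) − S(t)‖_F < tol` (absolute, default 1E-6) or `max_iter`
   (default 1000, far above the diameter of any network in scope).
3. **series oracle** — explicit depth-first enumeration of all directed
   walks up to length L, with a walk-count guard. It shares no linear
   algebra with the other two routes and exists purely as an independent
   verification instrument on small networks.

Defaults `α = 0.9, β = 0.1` weight multi-step signal flow heavily while
keeping the series convergent for degree-normalized weights; activity-level
verification runs (reporting output changes after an intervention) use
`α = β = 0.5`, weighting the basal intervention and network input equally.
All computation is double precision; nothing in the influence machinery is
random.

`S` includes the trivial diagonal self-influence `β` (`+` cycle
corrections). It is reported in full; SI-plot analysis reads single rows
and candidate selection excludes the output node itself, so the diagonal
never contaminates rankings.

## Link-weight normalization

`|W_ij| = 1/√(d_out(j) · d_in(i))` — the geometric mean of the source
out-degree and target in-degree. An arithmetic-mean variant is available
(`mean="arithmetic"`) but not default. Degrees are counted once on the
unweighted adjacency; self-loops count toward both the in- and the
out-degree of their node. Mutation edits are multiplications of the
*normalized* weights and never trigger a degree recount — the biological
reading is that an amplified protein pushes more signal through the same
wiring, not that the wiring changed.

## Interventions

* Inhibitor treatment: basal activity of the target set to −10 (link
  weights untouched). Any other basal value can be supplied; by linearity
  the induced output change is `Δx = S · Δb`, so the sign of the output
  response is always `−sgn(S_ij)` for an inhibitory basal shift.
* Constitutively activating mutation: in-link weights zeroed, out-link
  weights ×10 (equivalently attenuation with factors (0, 10)).
* Loss-of-function attenuation: in- and out-links scaled by arbitrary
  non-negative factors, e.g. (0.001, 0.001) for a 99.9% reduction, (0, 100)
  or (0, 0.01) for stronger asymmetric edits.

Order of operations in a full analysis: normalize weights → apply weight
edits → compute influence → apply basal interventions for activity-level
verification.

## SI-plot analysis

SPLO is the length of the shortest *directed* path from a node to the
output (BFS on reversed links). Unreachable nodes carry an explicit
marker and are excluded from grouping and selection — a node with no
directed path has exactly zero influence through the walk series, so it
cannot be a candidate.

Normalized influence is `sgn(S_ij)·log2(1 + |S_ij|/S_avg)` with `S_avg`
the mean of |S_ij| over sources with nonzero influence on that output.
The absolute-value mean was chosen because a signed mean can be near zero
(mixed activators/inhibitors), which would destroy the normalization; the
absolute mean keeps the log argument positive and the map strictly
increasing and sign-preserving, so within-group rankings by raw and
normalized influence coincide.

Candidate selection takes, per SPLO group, the top-k or top-⌈n%·size⌉
nodes in the requested direction (most positive for goals served by
inhibiting activators; most negative otherwise), unions the groups, and
removes the output and any caller-supplied exclusions (receptors, the
mutated node). The ceiling rule guarantees every non-empty group
contributes at least one candidate. Ties break lexicographically, making
selection deterministic. Multi-output candidate sets are combined by union
in the robustness protocol (the recovery statistics need the full
suggestion set) and can be intersected by callers that want targets common
to all outputs.

## Goal scoring

For goal directions `g_o ∈ {±1}` per output and intervention type, the goal
vector is `G_o = −g_o` for inhibition (inhibiting a positively influential
node decreases the output) and `G_o = +g_o` for activation. Then
`CD = 1 − cos(S, G) ∈ [0, 2]` and `CM = (∏_o sgn(S_o G_o)) · (1 + CD)`.
For the canonical two-output, all-(+1) goal this reduces to
`sgn(S₁)sgn(S₂)(1 + CD)`. A zero influence coordinate zeroes the sign
product: the node is classified "no effect" rather than ranked. Ranking
lists promising targets (CM > 0) ascending by CM, then undesirable ones
(CM < 0) with the least misaligned first. CM is invariant under positive
rescaling of the influence vector, so raw and normalized influence give
identical scores.

## Robustness protocol

A structural perturbation of integer level applies `2·level` trials, each
independently (p = 1/2) a degree-preserving double-edge swap
((a→b, c→d) → (a→d, c→b), signs traveling with the source link) or a
link-sign flip. Swaps that would create a self-loop or duplicate an
existing ordered pair are rejected *and consumed*, so the realized
topology distance `N_DL = Σ|A_ij − B_ij|` is stochastic around ~2·level
link changes — mirroring real curation noise where not every error is
independent. In critical modes the first swapped link / the flipped link
is always incident to a designated node set (the reference targets, or
the outputs).

Each experiment replicate perturbs the topology, reruns the entire
pipeline (normalization, influence, SPLO, top-10%-per-group selection by
default), and records N_DL, the recovery fraction R_T of the reference
target set, the hypergeometric tail p-value `P(X ≥ k)` for finding k
reference targets among N candidates from M nodes, and the enrichment
score `−log10 p`. Replicate RNG streams are spawned from the experiment
seed via `numpy.random.SeedSequence`, so tables are bit-reproducible.

## Synthetic data

The generators supply every network the tests need:

* the three toy motifs (cascade, crosstalk, negative feedback loop) whose
  influence values have closed forms;
* Erdős–Rényi signed digraphs (default 25% inhibitory links, the rough
  proportion seen in curated signaling maps) at sizes and densities chosen
  to match curated networks' link-to-node ratios (~2–3.5);
* Barabási–Albert digraphs oriented from each new node toward its
  attachment targets, so signal flows toward hubs (configurable);
* random DAGs and single-out-link "functional" digraphs used by the
  route-equivalence checks — DAGs make the walk series finite (complete
  enumeration), functional graphs make cyclic walk enumeration
  non-branching so the oracle can run hundreds of steps past the
  convergence tail.

What synthetic networks do *not* emulate: motif composition, modularity
and the specific feedback architecture of real signaling maps. Passing
tests therefore demonstrate the *mathematical* correctness of the pipeline
and the internal consistency of the protocol, not biological recovery
rates on curated networks; recovery on published networks requires their
edge lists as input (any SIF file works unchanged through the same CLI).
The robustness experiment plants its reference targets as a subset of the
unperturbed discovery (unperturbed R_T = 1 by construction), which isolates
the effect of the structural perturbation on recovery from the separate
question of whether SI-plot discovery matches an external gold standard.

## Numerical choices and problem sizes

* Spectral-radius guard via dense eigenvalues (exact at these sizes);
  threshold 1 applied directly, with iterative fallback advertised in the
  error.
* Walk-enumeration guard at 2×10⁶ walks.
* Route-equivalence checks use 200 random networks of up to 12 nodes;
  robustness runs use 50 replicates per level on a 60-node network and
  degree-preservation checks 10⁴ trials on a 200-node network — sizes at
  which the complete suite runs in seconds while exercising every code
  path at the link-to-node densities of curated signaling maps.
* All tolerances in tests are stated per check: 1E-12 for identities that
  are exact in floating point, 1E-10 for resolvent-vs-series limits, 1E-6
  for cross-route agreement at the iterative default tolerance.

## Known limitations

* Linear propagation ignores saturation, logic gates and dynamics; it
  predicts direction and relative magnitude of influence, not activity
  time courses.
* Single-target scoring only; synergy of target combinations is outside
  the model class.
* Different mutations of the same protein are indistinguishable — the
  topology carries no allele-level information.
* k / n% for candidate selection have no theoretical optimum and must be
  chosen empirically (the enrichment score offers a statistical criterion
  for tuning them).
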