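# Methods

## Model and scope

`rnabranch` samples the *branching pattern* of RNA secondary structures,
not structures of a particular sequence.  The state is a plane tree (root =
exterior loop, edge = helix, leaf = hairpin, non-root degree-1 node =
interior loop, non-root node of down degree ≥ 2 = multiloop).  This
abstraction is exact for the two combinatorial sequence families
A⁴(Y⁵ZA⁴YZ⁵A⁴)ⁿ with (Y,Z) ∈ {(C,G),(G,C)}, whose maximally paired
structures realize every plane tree with n edges; for natural sequences it
is a branching model only.  No folding engine, dot-bracket parsing, or
sequence-dependent NNTM terms (stacking tables, loop-length rules) are
included, and none are planned: the seven aggregate constants a, b, c, h,
f, i, g are the entire thermodynamic input.

## Energy and its reduction

For a tree with down-degree counts d_j, root degree r and n edges, the
loop-by-loop NNTM total

    d0·f + d1·i + Σ_{j≥2} d_j·(a + 4b(j+1) + c(j+1) + g(j+1)) + n·h + g·r

reduces, using Σ d_j = n and Σ j·d_j = n − r, to
α·d0 + β·d1 + γ·r + δ·n with

    α = f − a − 4b − c − g        β = i − a − 8b − 2c − 2g
    γ = −4b − c                   δ = a + 8b + 2c + h + 2g.

Both routes are implemented (`full_structure_energy` vs `tree_energy`) and
tested to agree within 1e−9 on all trees with ≤ 7 edges over random
parameter sets.  Coefficients are carried at full float precision; the
one-decimal values associated with the built-in Turner rows are display
rounding only.  The sampled distribution uses E = α·d0 + β·d1: δ·n is
constant at fixed n, and the exterior-loop term γ·r is deliberately
disregarded (it is small relative to the total for the long structures of
interest).  γ and δ are still computed and reported so users can judge the
size of what was dropped.

Gibbs weights are e^(−E) with E in raw kcal/mol — no RT divisor.  That is
a convention choice, not an oversight: α and β already absorb the scale at
which the built-in parameter sets were fitted, and an optional
multiplicative scale on E can be applied by scaling α, β directly.

## State space and bijection

Sampling runs on 2-Motzkin paths of length m = n − 1 (alphabet U, H, I, D;
every prefix has #D ≤ #U; totals equal).  The Deutsch bijection labels each
tree edge — U/D for the leftmost/rightmost of ≥ 2 siblings below a non-root
node, I for an only child of a non-root node, H for root edges and middle
siblings — reads labels in preorder and drops the leading H.  It transports
d1 to |x|_I and d0 to |x|_U + |x|_H + 1, so the path energy is
E(x) = α(|x|_U + |x|_H + 1) + β|x|_I.  The inverse is the stack algorithm
in `path_to_tree`; the pair is verified as mutually inverse on the full
enumerations up to n = 8 (1430 trees), and the m = 0 empty path maps to the
single-edge tree.

Trees serialize as balanced-parenthesis strings (one per line; child
subtrees concatenated left-to-right), chosen because the format is
unambiguous for ordered trees and diffable; an unlabeled Newick export is
provided for viewers.  Path files are one U/H/I/D string per line.  All
path positions in the API are 1-based, matching the lattice-path
convention.

## The chain

One step: pick move type l uniformly from {1..4}; then

* l=1 — pick one of the m−1 adjacent pairs; UD→HH with probability
  e^(−α)/(2(1+e^(−α))), HH→UD with probability 1/(2(1+e^(−α))).
* l=2 — pick one of the m positions; I→H with probability
  e^(−α)/(2(e^(−α)+e^(−β))), H→I with probability e^(−β)/(2(e^(−α)+e^(−β))).
* l=3 — pick two positions independently (ordered, i = j allowed); if both
  hold U or D, swap with probability 1/2, reverting if the result dips
  below the axis.
* l=4 — pick an adjacent pair; if exactly one symbol is U/D and the other
  H/I, swap with probability 1/2.

The 1/2 laziness is embedded in each Bernoulli, making the chain aperiodic;
irreducibility goes through the all-H hub path, which is also the default
initial state.  Moves l=1, l=2 and l=4 provably preserve validity, so the
O(m) prefix re-scan is performed only after l=3 swaps (no incremental
height bookkeeping in this version; the targeted m is at most a few
thousand).  At m = 1 the pair moves have no pair to pick and are implemented
as no-ops contributing to the diagonal, which preserves row-stochasticity
without inventing behaviour.  Identity swaps under l=3 (i = j or equal
symbols) likewise pass through the laziness and land on the diagonal.

Acceptance probabilities are evaluated in logistic form
(`scipy.special.expit`), e.g. e^(−α)/(1+e^(−α)) = expit(−α), so
user-supplied coefficients far outside the built-in range do not overflow.
Exact-distribution weights are normalized in log space via `logsumexp`.

### Randomness contract

`numpy.random.default_rng` (PCG64) seeded from the run configuration.  The
bulk runner consumes randomness in fixed chunks: per chunk, one integer
array of move types, then a 3×chunk float array serving as two index draws
and the Bernoulli per step; indices are derived from floats by scaling to
the relevant range.  The single-step API (`chain_step`) draws the same
layout per step.  The two entry points therefore consume the generator
stream differently; each is individually bit-reproducible given its seed,
within one build.  Cross-platform bit-identity is not promised.

## Exact oracles and diagnostics

For enumerable lengths (default caps: m ≤ 10 for distributions, m ≤ 8 for
transition matrices, i.e. up to C₉ = 4862 states) the package builds the
exact Gibbs law and the exact one-step kernel by summing move, index and
Bernoulli probabilities, then checks: detailed balance
π(x)P(x,y) = π(y)P(y,x) (machine precision), agreement of the leading left
eigenvector with the enumerated Gibbs law (TV < 1e−10), strong connectivity
of the transition graph plus self-loops (ergodicity), and spectral gap
1 − |λ₁| > 0.  These finite checks substitute numerically for the
asymptotic mixing-time theory; the proven O(m⁷) relaxation-time bound is an
asymptotic statement and is not reproduced.

## Statistics and placement

Per sampled tree: hairpins (d0), interior loops (d1), multiloops, maximum
multiloop branching (root excluded from both — it models the exterior
loop), exterior-loop degree, height, and diameter in edges.  "Maximum
ladder distance" has no canonical plane-tree definition; tree diameter
(each edge = one helix) is this package's operationalization and is
labelled as such.  Average contact distance is sequence-length-dependent
and not computable from the tree alone; it is omitted.

Dispersion summaries use the unbiased variance and nearest-rank quantiles
(no interpolation ambiguity on integer statistics).  Placement of an
observed value reports the percentile with the midpoint convention for
ties, and z = (observed − mean)/sd, with z flagged undefined on
zero-variance samples.

## Problem sizes and test design

Oracle-backed tests enumerate exhaustively where the state space permits:
bijection and counting to n = 8, reversibility/stationarity to m = 6 over
all six built-in (α, β) pairs plus (0, 0).  Stochastic checks use seeded
runs: 10⁶ chain steps at m = 4 must land within total variation 0.02 of the
exact law (and of the uniform law at α = β = 0), and 10⁶ single-step trials
from each m = 3 start state must match every exact kernel entry within
4σ binomial bounds.  These sizes make the full suite run in well under a
minute while leaving the stochastic tolerances comfortably non-trivial.

What passing these tests shows is fidelity of the sampler to the intended
Gibbs distribution on the plane-tree model — not fidelity of the plane-tree
model to any natural RNA ensemble, which would require sequence-dependent
energies outside this package's scope.

## Known limitations

* Single-chain diagnostics only; no parallel tempering or multi-chain
  convergence statistics.
* The practical mixing rate at large m is unknown; the spectral gap shrinks
  quickly with m (0.125 at m = 1, ≈ 0.0044 at m = 6 for the Turner-89 C/G
  coefficients), so long runs and generous burn-in are advisable for large
  structures.
* The sampled law sets γ = 0; models where the exterior-loop term matters
  materially are not represented.
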