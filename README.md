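# rnabranch

Monte-Carlo sampling of RNA secondary-structure **branching** under the
Nearest Neighbor Thermodynamic Model (NNTM), without reference to any
particular nucleotide sequence.

## The problem

Free-energy minimization under the NNTM is the workhorse for predicting RNA
secondary structure, but a single minimum-energy prediction gives no sense
of *dispersion*: is the predicted number of hairpins for a long sequence
unusually large for this energy model, or well within its typical range?
`rnabranch` answers that by sampling branching configurations from the full
Gibbs distribution the energy model induces, so that an observed statistic
can be placed as a percentile / z-score within the model's own dispersion.

## The model

Branching is abstracted as a **plane tree**: the root is the exterior loop,
each edge a helix, each leaf a hairpin, each non-root degree-1 node an
interior loop, and each non-root node of down degree ≥ 2 a multiloop.  The
NNTM's seven aggregate constants (a, b, c, h, f, i, g, all kcal/mol) reduce
to a linear energy on a tree *t* with *n* edges, d₀ leaves, d₁ interior
nodes and root degree *r*:

    E(t) = α·d₀ + β·d₁ + γ·r + δ·n,
    α = f − a − 4b − c − g,   β = i − a − 8b − 2c − 2g,
    γ = −4b − c,              δ = a + 8b + 2c + h + 2g.

With *n* fixed, δ·n is constant, and the exterior-loop term γ·r is small
and dropped, leaving E(t) = α·d₀ + β·d₁ and the Gibbs law
g(t) = e^−E(t) / Z over the Cₙ plane trees with n edges.

Sampling runs on the bijective **2-Motzkin paths** of length m = n − 1
(strings over U/H/I/D never dipping below the axis).  The Deutsch bijection
transports d₁ to the I-count and d₀ to (#U + #H + 1), so the energy becomes
E(x) = α(|x|_U + |x|_H + 1) + β|x|_I.  A four-move Markov chain —
UD↔HH rewrites, H↔I recolouring, U/D transpositions, and adjacent swaps of
a U/D with an H/I — is lazy, ergodic, and reversible for this Gibbs law;
exact small-instance enumeration (distribution, transition matrix, detailed
balance, spectral gap) is built in as an oracle suite.

## Worked example

Sample 99 000 branching configurations of 5-helix structures under the
Turner-89 C/G parameters (α = −0.9, β = −1.8), then ask whether an observed
structure with 5 hairpins is typical:

```sh
rnabranch sample --m 4 --turner 89 --yz CG \
    --steps 1000000 --burn-in 10000 --thin 10 --seed 42 \
    --out-prefix run --trees
rnabranch exact --m 4 --turner 89 --yz CG \
    --sample-file run.paths.txt --out-prefix check
rnabranch stats --trees-file run.trees.txt --observed hairpins=5
```

The diagnostics confirm the sampler is behaving (detailed-balance violation
at machine precision, empirical-vs-exact total variation under 2%):

```
"max_detailed_balance_violation": 1.08e-18,
"spectral_gap": 0.01035,
"tv_sample_vs_exact": 0.0184
```

and the placement report reads

```
hairpins=5: percentile 0.9972, z +3.184
```

— under this energy model a 5-edge structure has on average 2.21 hairpins
(sd 0.88), so observing 5 hairpins sits at the 99.7th percentile, more than
3 standard deviations above the model mean: strong evidence the branching
is atypical for the model rather than a generic outcome of it.

Every run writes a manifest JSON (seed, resolved configuration, move
tallies) sufficient to reproduce its outputs bit-for-bit within one build.

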