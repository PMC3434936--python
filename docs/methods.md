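# Methods

## The model

A taxon-area analysis treats geographic areas as the "taxa" of a
phylogenetic inference and each species as one binary character: cell
(i, j) of the matrix is 1 when species j occurs in area i. Area
relationships are then estimated exactly as a molecular phylogeny would
be, except that the characters are presences rather than sites.

The likelihood engine uses the two-state symmetric Mk model: a
continuous-time Markov chain in which a species appearing in an area's
ancestry (0 → 1) and disappearing from it (1 → 0) are equally probable,
with uniform stationary frequencies (½, ½). With the overall rate
normalised to one expected change per unit branch length, the transition
probabilities over a branch of length *t* at rate multiplier *r* are

    P(same)   = ½ (1 + e^(−2 r t))
    P(differ) = ½ (1 − e^(−2 r t))

Branch lengths are therefore in expected presence/absence changes per
species. Rate heterogeneity across species uses Yang's discrete gamma:
*k* = 4 equal-probability classes of Gamma(α, α), each represented by its
class mean (computed from regularised incomplete gamma functions), so the
mixture keeps unit mean rate. The optional +I variant adds a zero-rate
class of weight p_inv that can only generate constant columns.

Two deliberate modelling choices:

* **No ascertainment-bias (Mkv) conditioning.** Constant columns are
  data here: an all-zero column (a species absent everywhere — e.g. a
  hypothetical extinct taxon) shifts branch lengths and the likelihood.
  The extinct-taxa scenarios depend on this, so conditioned variants are
  out of scope. The mirror-image fact, that constant characters cost
  parsimony nothing, is asserted as a cross-engine invariant in the tests.
* **Symmetric rates only.** Gain ≠ loss models would break the
  equal-probability assumption the analysis is built on and are not
  offered.

Per-character likelihoods come from Felsenstein pruning over unique site
patterns (columns are compressed to patterns with counts; at ≤ 14 areas
no numerical rescaling is needed). The likelihood is rooting-invariant
under this reversible model, which the tests verify directly.

## Optimisation

On a fixed topology, branch lengths, α and p_inv are optimised by
iterated bounded one-dimensional searches (Brent), looping until the
relative log-likelihood gain falls below 1e-8. Bounds: branch lengths
[1e-6, 10], α [0.02, 100], p_inv [0, 0.99]. Starting lengths are Fitch
change counts scaled by the character count.

Coordinate ascent can stall on ridges when data are weak and branches
saturate, so the optimiser runs twice (parsimony-scaled and uniform 0.2
starting lengths) and polishes the better result with a joint
derivative-free Powell search over log branch lengths (and log α). Before
any optimisation the tree is put into a canonical rooted-binary form
(rooted on the first area's terminal branch, children ordered by smallest
descendant tip), which makes the fitted likelihood a function of the
unrooted topology alone rather than of how the caller rooted the input.
All of this is deterministic: the same topology and matrix always give
the same fit.

## Tree search

Heuristic search uses stepwise random-addition starting trees (addition
order randomised by the seed, insertions scored by parsimony) followed by
best-improvement hill climbing over the SPR neighbourhood (NNI
selectable). Under parsimony, all equally best topologies are collected —
the co-optimal set is closed under equal-score neighbour moves up to
`max_saved` (default 100). Under likelihood each candidate topology is
scored after branch-length optimisation: exactly (full tolerance) below
9 tips, and for larger trees with a short coarse pass, fully optimising
only a parsimony-ranked shortlist of 8 candidates per move and re-fitting
the leading final topologies at full precision. TBR swapping is not
implemented: on a 13–14 tip problem SPR with multiple random starts
reaches the same optima, and the tests pin the heuristic to exhaustive
enumeration at ≤ 6 areas.

Desk-scale defaults deliberately scale the published protocol down:
20 random-addition starts (not 1000) and 100 bootstrap replicates (not
2500), with the original scale reachable through configuration. The
nonparametric bootstrap resamples species columns (never areas) with
replacement, reruns a reduced search per pseudo-matrix, and maps
bipartition frequencies (percentages) onto the best tree from the full
search; trivial splits are not reported.

## Rooting

Two conventions, built to be interchangeable:

* **All-zero outgroup** — an artificial area with no species appended as
  an ordinary matrix row; ML and MP then root identically through it.
* **Lundberg rooting** — the unrooted optimum is rooted a posteriori on
  the terminal branch (at its midpoint, for determinism) of the area with
  the fewest species presences. A tie for the minimum is an error naming
  the tied areas; the caller must choose.

## Extinct-taxa scenarios

`add_extinct_taxa` appends all-zero columns with generated names;
`run_scenarios` runs the ladder round(fraction × n_species) for fractions
(0.5, 1, 1.5, 2) by default — round half up, so 0.5 × 1018 gives 509 —
each with the all-zero outgroup, and reports per level the fitted tree,
log-likelihood and Robinson–Foulds distance to the unaugmented baseline.
Scenario seeds derive as seed + level index, so one seed reproduces the
whole battery.

## Stochastic character mapping

A species history is a full realisation of the binary chain: states at
all nodes plus change points along every branch, drawn from the posterior
given the tips. Sampling is exact, in two stages:

1. **Joint node states.** The root state is drawn from its conditional
   posterior (pruning partials × uniform prior); descendants are drawn
   top-down from transition probability × subtree partial.
2. **Endpoint-conditioned branch paths.** On short branches (r·t ≤ 4),
   forward simulation with rejection — when the endpoints disagree, the
   first event time is drawn from the truncated exponential on [0, t]
   before simulating forward. Long branches (or a rejection budget of
   1000 exhausted) fall back to uniformisation, which for the symmetric
   two-state chain is particularly clean: the uniformised jump matrix is
   a deterministic flip, so the number of changes is simply a
   Poisson(r·t) count conditioned on the parity forced by the endpoints,
   and the change times are sorted uniforms. Both samplers target the
   same exact conditional law; the tests hold the zero-change fraction to
   its closed form in both regimes.

The mapping rate for a species defaults to its posterior-mean rate under
the fitted gamma(+I) mixture (`uniform_rate=True` forces rate 1).
Summaries over n_samples = 1000 histories (per-node presence
probabilities, per-branch expected occupancy, expected 0→1 and 1→0
counts) are exactly reproducible from the seed. The comparator is the
Fitch most-parsimonious state-set reconstruction (Swofford–Maddison
up-pass), checked against exhaustive minimal-labeling enumeration.
Direction counts are reported as gains and losses; reading them as
dispersal and extinction is left to the user.

## Similarity clustering

Pairwise area distances are either the mismatch proportion (default,
treating 0 and 1 symmetrically, consistent with the Mk symmetry) or
Jaccard distance on presence sets (0 when both areas are empty). UPGMA is
implemented directly so that ties in the minimum distance break by the
lexicographically smallest pair of sorted cluster name sets — a
documented, order-independent rule; scipy's average linkage serves as the
independent cross-check in the tests. Output is ultrametric with branch
lengths in distance units (merge height / 2 per join).

## Synthetic data

`simulate_matrix` evolves characters branch-wise under the chain: since
every event of the symmetric chain is a flip, per-branch change counts
are Poisson(r·t) and the child state is the parent XOR the count parity.
The true per-branch change counts are retained as oracles for the
mapping engine. Root states are uniform by default; gamma shapes draw
per-character rates from the continuous Gamma(α, α). Endemic characters
(a configurable fraction) are produced by bounded rejection until they
occupy 1–2 tips.

`lvv_fixture` is the package's stand-in for a 13-area regional survey
matrix (1018 species, 23 narrow endemics) built on a hard-coded truth
tree whose clades mirror the structure such an analysis recovers: a
river-valley/delta clade {P, BK, ZIB, XE, AH, BC}, steppe pairs {VP, ZP}
and {A, C}, BAC near the base and BOG on a long (1.0) basal branch. Two
of its parameters depart from the plain simulator, both to honour the
fixture's contract for *every* seed:

* the root presence probability is 0.9 (most surveyed species are
  widespread), and
* BOG's long branch decays its expected richness toward ½ while all
  other areas sit well above it, so BOG's row sum is the strict minimum
  (margin ≈ 4 standard deviations) and Lundberg rooting always selects
  it, while the branch stays short enough that BOG's attachment point
  remains recoverable at 1018 characters.

Fourteen of the 23 endemics are constrained (by rejection on low-rate,
root-absent characters) to occupy exactly the Baer-knoll pair ZIB+BK;
the rest occupy any 1–2 areas. Widespread characters are redrawn until
they occupy ≥ 3 areas so the endemic count is exact.

What the fixture does not emulate: real surveys have spatially
autocorrelated sampling effort, non-independent species (shared ecology),
and areas of wildly different size; none of that is in the generator, so
green tests show the machinery is correct and identifiable at realistic
sizes, not that any particular empirical matrix will behave as cleanly.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the sizes the
package's own analyses use: the full 13 × 1018 fixture for searches and
scenarios, 5 000 characters for gamma-shape recovery on 8 areas
(recovered α ∈ [0.4, 0.625] when simulating 0.5), 10^5 draws for the
path-sampler law, exhaustive enumeration at ≤ 6 areas for oracle
equality. Likelihood equality tolerances: 1e-10 against enumeration,
1e-5 between heuristic and exhaustive search (two independent optimiser
runs). SIMMAP segment sums must match branch lengths to 1e-9 relative.

## Known limitations

* Missing or polymorphic states are rejected, not modelled; the engines
  assume fully observed tips.
* The likelihood search is a heuristic: shortlist scoring can in
  principle skip an improving SPR move on large trees (never observed at
  ≤ 6 areas, where it is pinned to exhaustive search).
* Branch lengths at the 1e-6/10 bounds indicate no-signal or saturated
  data; the fit warns in the all-constant case but otherwise reports the
  bound silently.
* No Bayesian tree sampling, no time calibration, no constrained
  dispersal (DEC-style) models: the analysis deliberately works without
  temporal information.
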