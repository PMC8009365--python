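# Methods

`biomeshift` estimates biome shifts on dated phylogenies and asks how the
answer changes when species are forced into a single biome each.  This note
records the models implemented, the defaults chosen where the design was
genuinely open, and what the synthetic data do and do not establish.

## The range-evolution model

Biome occupancy evolves as a continuous-time Markov chain over the power
set of the biomes, the direct analogue of using biomes as "areas" in a
dispersal–extinction–cladogenesis analysis.  For `B` biomes the state space
has `2^B` states including the empty (null) range, which is anagenetically
absorbing, excluded from cladogenesis, and excluded from the root prior:
extant tips cannot be rangeless, so any probability mass reaching the null
state is simply lost likelihood.

Anagenetic rates, per Ma:

* gain of an available, unoccupied biome: `d` per occupied source biome
  (so a range of size `k` gains a particular biome at rate `k·d`; all
  pairwise dispersal multipliers are 1);
* loss of an occupied biome: `e` per biome; the last biome's loss enters
  the null state.

Cladogenesis differs by family.  Every allowed ordered daughter pair gets
base weight 1; `+J` adds founder-event jumps (one daughter keeps the
ancestral range, the other starts in one available biome outside it) with
weight `j ∈ [0, 3]` competing against those unit weights, and each
ancestor's row is normalised to a probability distribution.

* **DEC** — single-biome ancestors: sympatry (both daughters inherit);
  widespread ancestors: narrow vicariance (singleton vs complement) and
  subset sympatry (singleton vs full range).
* **DIVALIKE** — sympatry for single-biome ancestors, vicariance only for
  widespread ones.
* **BAYAREALIKE** — no cladogenetic range change: both daughters always
  inherit the full range.

At `j = 0` the `+J` tables coincide with the base tables term-for-term, so
the nested-model identity `lnL(+J, j=0) = lnL(base)` holds exactly, which
the tests assert without tolerance.

### Time stratification

Biome availability is a sequence of appearance ages (the packaged default,
`NZ_BIOMES`: Forest always, Open from 4 Ma, Alpine from 1.9 Ma).  A state
is allowed in a stratum iff all of its biomes exist there; because biomes
only appear, allowed sets shrink monotonically toward the past.  Branch
likelihood propagation is segmented at stratum boundaries; each segment
uses its stratum's `expm(Q·dt)` (dense scaling-and-squaring; the state
space is at most a few dozen states), and when the computation crosses
into an older stratum the conditional likelihoods of disallowed states are
set to zero without renormalisation — the standard treatment, which keeps
the likelihood a probability of the tip data.  An age exactly on a
boundary belongs to the younger stratum, so a node dated exactly at a
biome's appearance may already occupy it.

The root prior is uniform over the non-null states allowed at the root's
age.  This is a modelling default, not a data-driven choice; it is held in
one place (`TreeModel.root_prior`) and can be overridden by subclassing.

### Fitting and model choice

`fit_mle` maximises the pruning log-likelihood with bounded L-BFGS-B from
a fixed start grid — `(d, e) ∈ {(0.01, 0.01), (0.1, 0.1), (1, 1)}`, crossed
with `j ∈ {0.01, 0.5}` for jump models — under bounds `d, e ∈ [1e-12, 5]`
per Ma and `j ∈ [0, 3]`.  Everything is deterministic; refitting at the
returned optimum moves lnL by < 1e-6.  Each family is compared to its `+J`
variant by a one-tailed likelihood-ratio test, `2ΔlnL` against χ²₁ at
α = 0.05 (the ½χ²₀+½χ²₁ boundary mixture is available via
`boundary_mixture=True`; the plain upper tail is the default).  The three
survivors then compete on AIC = 2k − 2 lnL, with ties (within 1e-9) broken
toward fewer parameters and then DEC < DIVALIKE < BAYAREALIKE.

## Stochastic mapping and shift counting

Histories are sampled conditional on the tips in three standard stages:
node states root-to-tips from the pruning conditionals; cladogenetic
outcomes from the normalised tables weighted by the daughters' subtree
likelihoods; and each branch segment's anagenetic path by uniformization
between its sampled endpoint states (with an endpoint-conditioned
rejection sampler as fallback for numerically degenerate transition
probabilities; cap 10⁵ proposals).  Every run is reproducible from a
master seed via spawned `SeedSequence` streams, one per map, so results do
not depend on evaluation order.

A *shift event* is any anagenetic gain or loss plus any cladogenetic
outcome whose daughter range differs from the ancestor's (attributed to
the daughter's branch).  Both expansions and reductions count: a range
reduction is a real change in the set of biomes occupied, exactly like an
expansion seen from the other side.  Flags exclude losses or cladogenetic
events for sensitivity analyses.  `simplified` counting collapses each
branch's events to at most one — the convention needed to compare clades
against published per-clade shift counts — and the shift *rate* is the
simplified count divided by clade size.

One consequence of counting cladogenetic changes, found while building the
test fixtures: a single derived-biome tip is often explained by the model
as an anagenetic gain on the parent branch plus a vicariant split, which
touches more branches than a gain-plus-loss on one long branch.  Clumped
derived-biome subclades, not merely rare derived tips, are what depress
the simplified rate relative to tip-shuffled arrangements.

## The conservatism test

The tip-randomisation test permutes whole occupancy rows across taxa
(preserving the multiset of ranges, hence column sums and the specialist
count), reuses the observed maximum-likelihood parameters (refitting per
replicate is available but off by default), draws one stochastic map per
null replicate, and reports the fraction of null rates strictly greater
than the observed rate (the mean over 100 maps by default).  Conservatism
is called when that fraction is ≥ 0.95; a strict-inequality variant
(`strict=True`) is available.  The change in tendency toward conservatism
between codings is the difference of the two exceedance proportions, with
the percentage change relative to the single-coding proportion (undefined,
rendered "N/A", when that is zero).

Because simplified counts are small integers, the null exceedance
proportion has atoms: the production test is conservative (its realised
type-I error sits below the nominal 5%).  The calibration experiment in
the acceptance suite therefore uses five maps for the observed and every
null replicate — an exchangeable design in which the criterion fires for
about 1–5% of null-true replicates; the residual shortfall from 5% is the
discreteness, not a coding error.

## The D statistic

For each biome, occupancy is a binary trait.  `d_obs` sums, over internal
nodes, the absolute difference between daughter nodal values computed by
the branch-length-weighted averaging used for independent contrasts (an
equal-weights variant is a flag; zero-length cherry guards fall back to
plain means).  Two simulated references on the same tree scale it:

    D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian)

with the random reference a tip shuffle and the Brownian reference a
unit-rate Brownian trait thresholded at the observed prevalence exactly
(ones at the top ranks).  `p_random` is the raw fraction of permutation
values ≤ `d_obs` (no +1 smoothing), and D < 1 with `p_random` < 0.05 is
read as conservatism.  Traits fixed across tips carry no signal and return
an undefined result rendered "NA" — the same pattern the published signal
table shows for, e.g., a clade whose species all occur in Forest.  Because
both references are regenerated per dataset, the statistic is
self-calibrating: shuffled traits centre on D = 1 and Brownian-threshold
traits on D = 0, which the tests verify at 200 replicates.

## Meta-analysis statistics

Shift counts are floored to whole events before rating (rate = count /
clade size); specialist percentages are 100·s/n.  Group summaries use
linear-interpolation ("type 7") quantiles.  The single- vs multiple-coding
comparison across studies is a one-tailed Welch test (the unequal-variance
form is what reproduces the published t(7) from groups of 9 and 7; the
pooled test would give df 14), with degrees of freedom displayed by
nearest rounding.  The within-clade comparison is a one-tailed paired t
test with a guarded degenerate case (all differences equal).  Simple
linear regression returns slope, R², the F statistic `R²/(1−R²)·(n−2)`,
and residual/Q-Q diagnostics as data rather than plots.  The proportional
decline in shift rate is

    B_decline = (B_multiple − B_single) / B_multiple,

displayed as a whole-number percentage.  Net diversification uses the
method-of-moments estimators conditional on survival: `ln(n)/t` for stem
ages and `(ln n − ln 2)/t` for crown ages at extinction fraction ε = 0,
with the ε-corrected forms implemented for completeness.

The packaged clade-summary tables transcribe the published meta-analysis.
For the transcribed earlier studies the rate column is treated as data —
those studies' own reported rates, which do not always equal count/size —
while the focal clades' rates are recomputed at full precision.  The
published tables' display rounding is not internally consistent (one row
truncates where another rounds), so reproduction of printed per-clade
rates is asserted at printed precision (±0.01) rather than digit-exact.

## Synthetic data

`simulate_tree` draws constant-rate birth–death trees conditioned on the
number of surviving tips (via dendropy's simulator), then places the
present a uniform fraction of one further total-event waiting time after
the n-th lineage appears so no tip branch has zero length; for pure birth
the expected height from the first split is `(Σ_{k=2}^{n-1} 1/k + 1/(2n))/λ`,
the oracle used in the tests.  Defaults mirror the focal study's
conditions: 7–55 tips, multi-Ma depths, the three-biome staggered
availability, forest-rooted histories.

`simulate_history` runs the same stratified process forward by Gillespie
simulation, drawing cladogenetic outcomes from the family's table at each
node.  A lineage losing its last biome invalidates the replicate, which is
resimulated whole (cap 100) so clade size stays fixed — unbiased but
increasingly expensive conditioning: on large, slowly speciating trees the
expected number of null-range hits exceeds one and the acceptance-scale
200-tip recovery experiment therefore uses a faster speciation rate
(λ = 2/Ma), which shortens total lineage-time without touching the range
process being estimated.

Along every lineage a modal biome is tracked: each range change redraws
range proportions from a symmetric Dirichlet over the occupied biomes
(concentration 1 by default — maximally uninformative proportions), and an
optional re-weighting event (rate 0 by default) flips proportions without
a range change.  Branch-level transitions are classified by how each
coding would see them: disjoint replacements and modal-abandoning losses
(switches) and modal-moving gains are detected by both codings; gains or
losses that leave the modal biome unchanged are the single-coding false
negatives; modal changes without any range change are its false positives.
The "minor part of the range" notion is operationalised exactly as
"not the modal biome".

`make_meta_table` generates clade summary tables with a configurable
proportional decline (`effect`) acting only on each clade's non-specialist
fraction, so pure-specialist clades get identical rates under both codings
and a zero effect leaves the one-tailed paired test calibrated.

What the generators do **not** emulate: real range-proportion data (modal
weights are Dirichlet draws, not mapped distributions), biome-dependent
diversification, spatial structure within biomes, and phylogenetic or
dating error.  Passing tests therefore establish internal correctness and
calibration of the estimators under the assumed process, not robustness to
violations of it.

## Problem sizes in the shipped experiments

The acceptance experiments use 3–4-tip trees for exact enumeration checks,
10⁴ maps for the sampling/marginal agreement, one 200-tip clade for
parameter recovery, 50 twelve-tip clades for the coding closure, 200
replicates for D calibration, and 100 null-true replicates × 199 nulls for
the conservatism calibration — sizes chosen to keep each experiment's
Monte-Carlo error well inside its acceptance band.
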