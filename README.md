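# biomeshift

Estimating biome shifts on dated phylogenies, and testing how strongly the
common *single-biome-per-species* simplification biases the result.

Many plant species occupy more than one biome — a tussock grass may grow
both in open grassland and above the treeline — yet biome-shift and
biome-conservatism analyses frequently force each species into its single
"modal" biome before fitting anything.  `biomeshift` implements both tip
codings end-to-end over the same machinery so they can be compared like for
like, for researchers in historical biogeography and macroevolution:

* **Range-evolution models** (`ranges`, `fitting`): time-stratified
  continuous-time Markov chains over biome-occupancy sets — DEC, DIVALIKE
  and BAYAREALIKE cladogenesis, each with an optional founder-event jump
  (`+J`) — with a Felsenstein pruning likelihood, maximum-likelihood
  fitting, one-tailed LRTs of each family against its `+J` variant, and AIC
  selection.  Biome availability windows (e.g. Forest always, Open from
  4 Ma, Alpine from 1.9 Ma) mask states and transitions per time stratum.
* **Biogeographic stochastic mapping** (`mapping`): full occupancy
  histories sampled conditional on the tips; biome shifts counted raw or
  simplified (at most one shift per branch), with shift rate = shifts per
  species.
* **Conservatism tests** (`conservatism`, `signal_d`): the tip-
  randomisation null test (observed shift rate vs rates from shuffled
  occupancy rows; conservatism when ≥95% of nulls exceed the observation)
  and the D statistic for binary traits, scaled so random tip arrangements
  give D = 1 and Brownian-threshold traits give D = 0.
* **Meta-analysis statistics** (`meta`): shift rates and specialist
  percentages, type-7 group quartiles, one-tailed Welch and paired t tests,
  simple regression with diagnostics, diversification-rate estimators, and
  the proportional decline in shift rate
  `B_decline = (B_multiple − B_single) / B_multiple`.  Clade-summary tables
  transcribing the published meta-analysis ship as package data.
* **Synthetic data** (`simulate`): birth–death trees, forward simulation of
  the stratified range process with complete truth retained, Dirichlet
  modal-biome weights, a typology of transitions by which coding detects
  them, and synthetic meta-analysis tables with controllable effect size.

## Worked example

Simulate a 16-tip clade under the three-biome New Zealand availability
(DEC, d = 0.15 gains/Ma, e = 0.03 losses/Ma), then analyse it under both
codings:

```python
from biomeshift import *

cfg = SimulationConfig(n_tips=16, seed=5, model=ModelSpec("DEC", d=0.15, e=0.03))
tree = simulate_tree(cfg)
truth, occ = simulate_history(tree, cfg)          # multiple-biome tips

best = select_best(fit_all(tree, occ, cfg.avail))  # LRT vs +J, then AIC
bm = bsm_rates(tree, occ, best, cfg.avail, n_runs=100, seed=1)

occ_single = collapse_to_modal(occ, truth.tip_weights)
best_s = select_best(fit_all(tree, occ_single, cfg.avail))
bs = bsm_rates(tree, occ_single, best_s, cfg.avail, n_runs=100, seed=1)

print(best.spec.name, bm.mean_rate, bm.sd_rate)
print(best_s.spec.name, bs.mean_rate, bs.sd_rate)
print(b_decline(bm.mean_rate, bs.mean_rate).percent)
```

Output:

```
DEC 0.459375 0.05983919423477114
DEC+J 0.27625 0.03787689389204309
40
```

Nine of the sixteen simulated species are biome specialists.  Under
multiple-biome coding the selected model is plain DEC and stochastic
mapping yields a mean simplified shift rate of 0.46 ± 0.06 shifts per
species; collapsing every species to its modal biome selects DEC+J and
drops the rate to 0.28 ± 0.04 — a 40% proportional decline
(`B_decline = 0.40`), the headline effect the package exists to quantify:
single-biome coding cannot see expansions into minor biomes, so it counts
systematically fewer shifts.

The same objects feed the conservatism test
(`conservatism_test(tree, occ, best, cfg.avail, ConservatismConfig(...))`)
and per-biome phylogenetic signal
(`d_statistic(tree, occ.presence[:, 1], 1000, 1000, seed=0)` → here
D = −0.07 with p_random = 0.09 for the Open biome: clumped, but not
significantly so at 16 tips).

A thin CLI wraps the same functions: `biomeshift fit`, `bsm`,
`conservatism`, `dstat`, `meta`, `simulate` (see `biomeshift --help`).

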