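# Methods

This note documents the models implemented in `evorescue`, the parameter
choices and their rationale, the numerical decisions that were genuinely
open, and what the desk-scale tests do and do not demonstrate.

## Landscape model

Environmental landscapes are stationary Gaussian random fields on the unit
torus, synthesized in the frequency domain: white noise is filtered by the
square root of the power spectrum of an isotropic Gaussian correlation
kernel `exp(-d²/(2 l_e²))` evaluated with torus distances. Frequency-domain
synthesis makes periodicity exact (no seam at the wrap boundary; the tests
verify wrap-adjacent rows correlate like interior-adjacent rows). The field
is then affinely rescaled so the realized grid has sample mean `mu_e` and
SD `sigma_e` exactly; because of this post-hoc rescale the generator's
amplitude parameter is inert and is retained only for configuration
fidelity. With `sigma_e = 0` the landscape is exactly constant.

Coordinates live in `[0, 1)` per axis; cell `(i, j)` of an `R x R` grid
covers `[i/R, (i+1)/R) x [j/R, (j+1)/R)` and lookups are nearest-cell
(floor), with no interpolation — a discrete habitat-map semantics that the
binary loss maps require. Default resolution is 128 (64 in reduced
profiles); the environment is effectively piecewise constant at a scale
well below the environmental autocorrelation length.

Realized spatial autocorrelation is summarized by Geary's C with binary
rook adjacency on the torus. Rook weights are the simplest standard choice;
C ≈ 1 for independent values, < 1 for positive autocorrelation. The
generator produces monotonically lower C for larger `l_e` (tested over
seeds).

Warming is a deterministic linear ramp added at lookup time: total shift
`delta_e` accrued over 100 generations (`delta_e/100` per generation), then
held. `delta_e = 3` with `sigma_e = 1` means warming by three landscape
SDs; the no-change control is `delta_e = 0`.

## Habitat loss

A loss map is a second Gaussian random field (autocorrelation length
`l_hl`) thresholded at its empirical `p_l` quantile: the `round(p_l R²)`
cells with the highest field values are destroyed. The destroyed fraction
therefore equals `p_l` to within one cell. All study scenarios destroy
`p_l = 2/3` of the landscape; `l_hl` controls fragmentation — larger
`l_hl` yields larger, more contiguous remnant patches (verified with a
torus-aware connected-component oracle). Destroyed cells are permanently
non-habitat: individuals standing on them at the loss event die (their
genotypes leave the population), and habitat choice never accepts a
candidate position there (fitness 0).

Scenario properties use the trimmed-breadth convention: `B` is the range of
values strictly inside the set's own (2.5th, 97.5th) percentile band, with
percentiles computed by linear interpolation of order statistics (the
common type-7 rule, shared with the test oracles); `delta_Be = B2 - B1` and
`delta_mu_e` is the remaining-habitat mean minus the full-grid mean. The
breadth difference is reported in environment units (not as a proportion);
with unit-SD landscapes the two readings differ only by a constant factor.

Scenario sets are chosen by weighted density sampling: candidates are
generated by randomizing `(l_hl, seed)` with `l_hl` log-uniform on
[0.02, 0.3] (so fragmented and contiguous scenarios are both well
represented), scored on all three properties, and selected without
replacement with probability proportional to the inverse of a Silverman-
bandwidth kernel density estimate of the focal property — flattening the
focal marginal so the whole range is covered — while the two non-focal
properties are constrained to ±0.25 pooled SD around their candidate-pool
means. These bands are tight: only a few percent of candidates are jointly
eligible, which is why the candidate pool must be one to two orders of
magnitude larger than the selection (the full profile uses 100,000
candidates for 50 selections; desk profiles use 600–4,000). The interaction
designs instead pin the second property near its pool 25th or 75th
percentile (±0.1 pooled SD) while the focal property is flattened and the
third held near its mean.

## Individual-based model

Non-Wright-Fisher, overlapping generations, diploid hermaphrodites on the
torus. Per generation the event order is fixed: (1) reproduction, (2)
habitat choice for everyone including newborns, (3) viability selection,
(4) aging with a hard cap of 10 generations, (5) counter updates that drive
the selection ramp and warming offset. Extinction is absorbing.

* **Mating** — each individual takes its strictly nearest neighbor within
  3σ_p as mate (no pairing exclusivity; hermaphroditism makes roles
  symmetric), else skips reproduction. Distance ties break to the lowest
  individual id, which makes trajectories reproducible; the vectorized
  nearest-neighbor search resolves ties among the nearest eight candidates,
  which covers the coincident-position case that offspring placement
  creates.
* **Reproduction** — Poisson(λ₀) offspring per mating; each offspring gets
  one recombinant gamete per parent (free assortment between the 10
  simulated linkage groups, per-site crossover rate 1e-8 within) and is
  placed exactly at the first parent's position. QTL mutations (effects
  Normal(0, σ_QTL), rate μ·p_QTL per site per gamete) occur only during
  burn-in; afterwards the allele registry is frozen and the segregating
  count can only decrease. The 10 neutral linkage groups are declared but
  not simulated.
* **Phenotype** — strictly additive: the sum of allele effects over both
  haplotypes, homozygotes counting twice.
* **Fitness** — the survival probability combines a competition factor
  `2π σ_p² K / C_i` and a Gaussian matching factor
  `exp(-((P_i - e)σ_b)²/(2σ_f²))`, clamped to [0, 1] because it is used as
  a Bernoulli survival probability. σ_b scales the phenotypic deviation, so
  small σ_b means weak environmental selection and σ_b = 1 recovers the
  plain Gaussian. With no neighbors (C_i = 0) the competition factor is
  taken as 1, so an isolated individual survives according to its matching
  component alone; the alternative (treating the factor as its cap) would
  make isolated individuals immortal regardless of mismatch. At uniform
  density N ≈ K the expected competition load is ≈ 2π σ_p² K, making the
  competition factor ≈ 1 exactly at capacity — this is how the
  landscape-wide K emerges from purely local density dependence.
* **Selection ramp** — linear in generation from σ_b0 = 0.1 at generation 0
  to 1 at the end of burn-in (only the endpoints are fixed by the design;
  linearity is the simplest monotone choice). The ramp is scaled to the
  configured burn-in length so shortened desk burn-ins preserve its shape.
* **Habitat choice** — one candidate per individual per generation,
  uniform offsets in (−σ_p, σ_p) per axis, torus-wrapped; the move is
  accepted only if fitness at the candidate (competition re-evaluated
  against the current, pre-move neighbor configuration) strictly exceeds
  fitness at the current position. All candidates are evaluated against the
  same configuration and accepted moves applied synchronously — the only
  order-free (and vectorizable) reading; a sequential randomized-order
  variant would differ only at second order in the per-step displacement. A
  configuration flag (`habitat_choice_fitness = "match_only"`) restricts
  the comparison to the matching component, since whether the original
  implementation included the competition factor is not determinable; the
  default uses full fitness.

Spatial queries use a periodic cKD-tree (competition pairs, nearest
neighbors, candidate neighborhoods), which agrees with the O(n²)
brute-force oracle to 1e-12 and keeps a generation step at ~10 ms for
N ≈ 500, so a 1,500-generation burn-in costs ~20 s on one CPU.

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| K | 1000 (500 desk) | landscape-wide carrying capacity via local density dependence |
| σ_p | 0.02 | perception distance (landscape units); interaction radius 3σ_p |
| σ_f | 0.5 | matching-function SD (environment units); sets selection strength |
| σ_QTL | 0.1 | SD of QTL effect sizes (phenotype units) |
| μ·p_QTL | 1e-7 | per-site mutation rate (burn-in only) |
| λ₀ | 0.45 | mean offspring per reproduction event |
| max_age | 10 | hard survival cap (generations) |
| burn_in | 10,000 (1,000–1,500 desk) | initialization length |
| σ_b0 | 0.1 | selection-ramp start |
| Δe | 3 | total warming (landscape SDs) over 100 generations |
| l_e | 0.1 | environmental autocorrelation length |
| μ_e, σ_e | 0, 1 | environment scale: Δe and σ_f are in landscape-SD units |

λ₀ and σ_f were calibrated once so that (a) burn-in never goes extinct at
the desk sizes and (b) persistence under a central loss scenario with
warming is intermediate (0.2–0.8), the regime where landscape properties
can matter; the defaults above already satisfy both at K = 500. Densities
well below ~2 expected neighbors within 3σ_p (e.g., K ≈ 150 at σ_p = 0.02)
sit under a mate-finding Allee threshold and are not viable; small-K smoke
configurations must raise σ_p accordingly.

## Outcome metrics

Per replicate run: persistence (population alive at the final census, 100
generations after the end of the 100-generation warming ramp — i.e., census
at loss + 200; the alternative "100 generations after loss" horizon is a
config knob), time to extinction (first post-loss generation at size 0;
censored when persisting), final/pre-loss population-size and
segregating-allele ratios (the latter is ≤ 1 by the mutation freeze), the
mean per-individual per-generation displacement over the post-loss period
(non-movers contribute 0; averaging over all individual-generations makes
the metric comparable across scenarios with different acceptance rates),
and final phenotypic variance. Persistence proportions per scenario carry
their trial counts for the binomial likelihood.

## Inference

The inference layer follows the Model → `fit()` → Results convention of
mainstream statistical packages — a model object built from data, a results
object carrying draws, intervals, diagnostics and `summary()` — because it
is the one genuinely fitted-to-data component; the simulator and generators
are procedural, since nothing there is estimated.

Both persistence models use a binomial likelihood aggregated per scenario —
an exact regrouping of the per-trial Bernoulli likelihood — with Normal(0,5)
priors on fixed effects and half-Normal(0,2) on the between-landscape SDs
(weakly informative and proper on the logit scale; the hierarchical effects
are zero-mean normals with estimated SDs). Landscape properties are
standardized (sample SD, n−1) before fitting so slopes are comparable
across properties; the transform is stored for back-mapping.

Sampling is an adaptive blocked Metropolis-within-Gibbs scheme written for
this model family: separate random-walk blocks for the fixed effects and
the log-SDs, per-landscape random-effect blocks updated simultaneously
(valid because the likelihood factorizes over landscapes given the fixed
effects), and four likelihood-invariant interweaving moves — shifting a
fixed effect with a compensating shift of the non-centered effects, and
rescaling a SD with compensating rescaled effects — that decorrelate the
hierarchy and give near-independent mixing of the hyperparameters. Proposal
scales adapt during warmup toward standard acceptance targets and are
frozen afterwards. Defaults: 4 chains, 1,500 warmup, 5,000 iterations
thinned by 4 (hierarchical) or 12,000 thinned by 12 (pure random-walk
fixed-effects models, which need heavier thinning). Convergence thresholds:
split R-hat < 1.01 and bulk ESS > 400 per reported term, no divergences (the
sampler has none by construction; the count is reported as 0); a fit
failing them raises an error carrying the diagnostics. Near the `tau -> 0`
boundary mixing is slower and longer chains are needed. Parameter-recovery
tests scale the simulated group effects to their exact target SD so that
recovery checks the sampler rather than the luck of one draw of group
effects; an independent variational-Bayes mixed-logit fit (statsmodels)
cross-checks the fixed-effect posteriors.

## Study designs and problem sizes

The full study shape — 50 landscapes × 50 scenarios per property × 100
replicates, 10,000-generation burn-in, 100,000 candidate scenarios — is
retained as `FULL_PROFILE` and is cluster-sized. Package defaults and tests
use desk profiles chosen as this package's own working sizes: the main
desk profile is 5 × 15 × 20 with a 1,500-generation burn-in at K = 500; the
direction-recovery acceptance test uses 3 landscapes × 8 scenarios per
property × 3 replicates (one control replicate), 1,000-generation burn-in,
64×64 grids, which completes in minutes on one CPU and recovers the
qualitative effect directions. One burn-in is run per (landscape,
replicate) and shared across that landscape's scenarios; every run's seed
derives from the master seed and its (stage, landscape, scenario,
replicate) key via `SeedSequence`, so any cell is independently
reproducible and process-parallel execution is bit-identical to serial.

## What the synthetic data do and do not show

The generators emulate the study's own world: a single smooth environmental
gradient, binary instantaneous loss, deterministic linear warming, no
environmental stochasticity or seasonality, no habitat-quality gradation,
no cost of crossing the destroyed matrix, and a single polygenic trait.
Passing tests therefore demonstrate internal consistency of the model and
pipeline — local adaptation emerges, loss structure shifts persistence in
the expected directions, the inference machinery recovers known effects —
not that real landscapes behave this way. Magnitudes of the fitted slopes
at desk scale are not comparable to full-scale values (fewer landscapes,
scenarios and trials give wide, landscape-dominated posteriors); only signs
and relative orderings are stable enough to test at this size.

## Known limitations

* Nearest-neighbor-only mating and one candidate move per generation are
  strong simplifications of dispersal; both are structural choices of the
  study design, not fitted quantities.
* The loss maps and landscapes share a generator family; real land-use
  change has covariates (slope, accessibility) that are not modelled.
* Mate-distance ties beyond the eight nearest candidates resolve by tree
  order rather than global lowest-id (measure-zero except for large stacks
  of coincident individuals).
* The random-walk fixed-effects sampler is robust but slow per effective
  sample; hierarchical fits should prefer the blocked sampler path.
* `delta_Be` is bounded above by construction (loss cannot widen the
  trimmed breadth beyond sampling noise), so its candidate distributions
  are left-skewed; the KDE flattening mitigates but does not remove this.
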