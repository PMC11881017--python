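# evorescue

Evolutionary rescue of locally adapted populations under structured habitat
loss and a changing climate — an individual-based simulation study as a
reusable Python package.

## The scientific problem

Habitat loss is rarely spatially random: it clusters in space and within
particular environmental conditions (valleys rather than ridges, warm
lowlands rather than cool uplands). For a population locally adapted to a
spatially autocorrelated environmental gradient, the *pattern* of loss
determines which locally adapted genotypes survive the loss event and
therefore how much standing genetic variation remains for adapting to
subsequent environmental change. `evorescue` quantifies how three landscape
properties of the lost habitat affect the probability that a population
persists through a warming event:

* **ΔB_e** — change in the trimmed environmental breadth of remaining
  habitat (range of values strictly inside the 2.5th–97.5th percentile
  band), ΔB_e = B₂ − B₁;
* **Δμ_e** — shift of the mean environmental value of remaining habitat,
  Δμ_e = μ_e′ − μ_e (positive when cool cells are preferentially destroyed);
* **l_hl** — the autocorrelation length of the loss map: large l_hl gives a
  few large remnant patches, small l_hl a highly fragmented landscape.

## The model

Diploid hermaphroditic individuals live on the unit torus over a periodic
Gaussian-random-field environment (mean μ_e, SD σ_e, autocorrelation length
l_e). Each generation they mate with their nearest neighbor within the
perception radius 3σ_p (Poisson(λ₀) offspring placed at the first parent's
position), take one habitat-choice step (a uniform candidate displacement
within ±σ_p per axis, accepted only if fitness improves), and survive with
probability

    w_i = min(1, (2π σ_p² K / C_i) · exp(−((P_i − e(x_i, y_i)) σ_b)² / (2σ_f²)))

where C_i = Σ_j exp(−d_ij²/(2σ_p²)) is the local competition load (pairs
within 3σ_p), K the landscape-wide carrying capacity, P_i = Σ_l q_l the
additive polygenic phenotype (QTL effects q_l ~ Normal(0, σ_QTL) on 10
simulated linkage groups of 50,000 sites), and σ_b a selection ramp rising
to 1 over the burn-in. Survival is further capped at 10 generations of age.
After the burn-in establishes local adaptation, a quantile-thresholded
autocorrelated loss map destroys 2/3 of the landscape in one generation and
a linear warming ramp (total Δe over 100 generations) begins; mutation is
frozen, so rescue can come only from movement and standing variation.

Persistence over replicate populations is then analyzed with Bayesian
logistic models: per landscape property V a random-slope/intercept model

    logit(p_persist) = (β₀ + β₀^{(g)}) + (β₁ + β₁^{(g)}) · V,
    β^{(g)} ~ Normal(0, τ),

and for property pairs a fixed-effects interaction model
logit(p) = β₀ + β₁V₁ + β₂V₂ + β₃V₁V₂, both with binomially aggregated
trials, Normal(0, 5) priors on fixed effects and half-Normal(0, 2) on the
hierarchical SDs, sampled by an adaptive blocked Metropolis-within-Gibbs
sampler with interweaving moves (diagnostics via `arviz`).

## Worked example

```python
import numpy as np
from evorescue import (LandscapeParams, generate_landscape, generate_loss_map,
                       scenario_properties, SimConfig, run_burn_in, run_scenario,
                       score_trajectory)

landscape = generate_landscape(LandscapeParams(mu_e=0, sigma_e=1, l_e=0.1, seed=1))
print(f"Geary's C = {landscape.gearys_c:.4f}")          # Geary's C = 0.0030

cfg = SimConfig(K=500, burn_in=1500)
state = run_burn_in(landscape, cfg, seed=11)
corr = np.corrcoef(state.phenotype, state.env_values())[0, 1]
print(f"N = {state.n}, corr(P_i, e) = {corr:.2f}")      # N = 464, corr(P_i, e) = 0.97

scenario = generate_loss_map(l_hl=0.08, p_l=2/3, resolution=128, seed=5)
props = scenario_properties(landscape, scenario)
print(f"dBe = {props.delta_Be:.2f}, dmu_e = {props.delta_mu_e:.2f}")
                                                        # dBe = -1.39, dmu_e = -0.17

persisted = sum(
    score_trajectory(run_scenario(state, scenario, cfg, seed=100 + r, delta_e=3.0)).persisted
    for r in range(6)
)
print(f"persisted {persisted}/6 replicates")            # persisted 2/6 replicates
```

The burn-in establishes strong local adaptation (phenotype–environment
correlation ≈ 0.97) with the population regulated near K; under a central
loss scenario plus a 3-SD warming ramp, persistence is intermediate — the
regime where the landscape properties of the loss decide the outcome. A
full study (scenario selection by weighted density sampling, replicate
simulations, hierarchical fits) runs through
`evorescue.experiment.run_main_design`, or from the shell:

```bash
evorescue simulate --config study.cfg --out study_out/
evorescue analyze --persistence study_out/persistence.tsv --property l_hl --out study_out/
```

At a reduced desk scale (3 landscapes × 8 scenarios per property × 3
replicates), the fitted posterior mean slopes recover the headline
directions: positive for l_hl (larger patches help persistence), negative
for ΔB_e (losing environmental breadth hurts), with the l_hl effect the
largest in magnitude.

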