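# occugam

Bayesian dynamic occupancy modelling for large-scale, replicated
presence/absence surveys, with a **time-evolving thin-plate spline
occupancy surface**, **Markov stop-level availability**, **Gibbs
variable selection** over climate covariates, and imperfect detection.

The motivating design is a roadside survey programme: each route (site)
is visited once per year, its stops are aggregated into `J`
consecutive replicate groups, and a species' per-group detection
history is recorded. The model separates four processes that such data
confound:

1. **Occupancy** — is the species present on the route at all in year
   `t`? `logit ψ_it = f_t(x_i) + Σ_q ω_q β_q X_itq`, where `f_t` is a
   thin-plate regression spline over route coordinates whose
   coefficients follow a random walk across years, and the `X` are five
   standardized climate covariates plus their squares. Binary
   indicators `ω` select covariates under a marginality constraint (a
   squared term can only enter together with its linear term).
2. **Availability** — given presence, is the species available for
   detection at each replicate group? A Markov chain along the route:
   first group available with probability `π_t`, later groups with
   probability `θ'` after an available group and `θ` after an
   unavailable one.
3. **Detection** — given availability, is it detected?
   `logit p = α₀ + α₁·wind + α₂·first_year + α₃·protocol + η_obs`, with
   a normal random observer effect `η_obs`.
4. **Range dynamics** — posterior occupancy maps on a buffered-hull
   grid and derived index series: proportion of area occupied,
   occupancy-weighted mean breeding latitude, and southern/northern
   range limits.

Inference is by a blocked Gibbs sampler: joint forward-filter
backward-sample updates of the latent presence/availability layers,
Pólya-Gamma augmentation for every logistic layer, conjugate updates
for availability and smoothing parameters, and a pilot-run pseudo-prior
scheme for the variable-selection indicators.

## Worked example (CLI)

```bash
occugam simulate --fixture selection --out-dir demo --seed 20240601
occugam fit      --out-dir demo --seed 7 --n-chains 2 --n-warmup 400 --n-samples 600
occugam predict  --out-dir demo --seed 7 --thin 10
occugam indices  --out-dir demo --seed 7
occugam ppc      --out-dir demo --seed 7 --thin 8
```

This simulates 300 routes over 6 years with two active climate
covariates (linear coefficients 1.0 and −0.7) and eight inert ones,
fits the model, writes posterior occupancy maps
(`occupancy_maps.csv`), range-index series (`range_indices.csv`) and a
Freeman–Tukey posterior predictive check (`ppc.csv`). On this fixture
the fitted run typically reports a central global Bayesian p-value
(no evidence of misfit), posterior inclusion probabilities near 1 for
the two active covariates and low for the inert ones, and 95%
intervals covering the generating `θ = 0.4`, `θ' = 0.8` and
`α₀ = 0.8`; the test suite verifies these properties over 20
independent replicates.

Every subcommand takes `--config config.yaml` (flags override file
values) and logs the package version, seed and a configuration digest.

## Library example

```python
from occugam import (SimDesign, simulate_dataset, build_tprs_basis,
                     MCMCConfig, estimate_pseudopriors, fit, bayesian_pvalue)

design = SimDesign(n_sites=200, n_periods=6, K=12)
data, truth = simulate_dataset(design, seed=1)
basis = truth.basis
gvs = estimate_pseudopriors(data, basis)
samples = fit(data, basis, gvs, MCMCConfig(n_chains=2, seed=1))
print(samples.diagnostics)                      # R-hat / ESS table
print(samples.stacked("omega").mean(axis=0))    # posterior inclusion
print(bayesian_pvalue(samples, data, basis, seed=1, thin=8))
```

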