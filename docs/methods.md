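# Methods

## Model

Data: `N` routes with coordinates, surveyed in a subset of `T` years;
each surveyed route-year yields a binary detection history
`h_{i·t} ∈ {0,1}^J` over `J` consecutive replicate groups (default
`J = 5`), plus survey covariates (wind class, observer identity,
first-year-observer flag, protocol change flag) and five
route-by-year climate covariates.

**Occupancy.** `z_it ~ Bernoulli(ψ_it)` with

```
logit ψ_it = f_t(lat_i, lon_i) + Σ_{q=1}^{10} ω_q β_q X_itq
```

`X` holds the five standardized climate covariates and their squares.
`f_t` is a rank-`K` thin-plate regression spline (TPRS): the kernel
`η(r) = r² log r / (8π)` on centred, commonly scaled coordinates is
eigen-reduced to `K − 3` leading directions, the sum-to-zero-like
affine constraints are absorbed with an SVD null basis, and the design
is `[U D Z | 1, lat, lon]` with penalty `S = blockdiag(ZᵀDZ, 0₃)`.
The penalty null space is exactly the affine functions
`{1, lat, lon}`. Coefficients evolve as a first-order random walk
across years, `ν_t = ν_{t−1} + ε_t`, `ε_t ~ N(0, σ²_rw I)`, so the
surface changes smoothly in time; the smoothing parameter `λ`
penalizes `ν_tᵀ S ν_t` and gets a conjugate Gamma prior
(shape 0.05, rate 0.005); null-space coefficients get a proper
`N(0, 10²)` prior in place of the improper flat prior, which keeps
every conditional proper and the prior simulable (needed for the
successive-conditional sampler validation).

**Availability.** Given `z_it = 1`, availability along the route is a
Markov chain: `y_{i1t} ~ Bern(π_t)`, and for `j > 1`
`y_{ijt} ~ Bern(θ'}` if `y_{i,j−1,t} = 1` else `Bern(θ)`. Given
`z_it = 0`, all `y = 0`. Beta(1,1) priors.

**Detection.** Given `y_{ijt} = 1`, `h_{ijt} ~ Bern(p_it)` with
`logit p_it = α₀ + α₁ wind + α₂ first_year + α₃ protocol + η_{obs(i,t)}`,
`η ~ N(0, σ²_obs)`; `α ~ N(0, 10)`, half-normal scale-2 priors on
`σ_rw` and `σ_obs`. Given `y = 0`, `h = 0` (no false positives).

**Variable selection.** Each covariate pair (linear `m`, squared `m²`)
has indicators with prior mass ½ on (0,0), ¼ on (1,0), ¼ on (1,1);
the marginality constraint `ω_{m²} ≤ ω_m` is structural. Marginally
the prior inclusion probability is ½ for linear and ¼ for squared
terms. Active coefficients get a `N(0, 100)` slab; inactive ones are
sampled from pseudo-priors so the indicator updates mix: pseudo-prior
means/scales come from a fast pilot fit of a simplified model (static
smooth with fixed ridge, shared `π`, no observer effects), maximised
under working normal priors — `N(0, 2²)` on the standardized climate
coefficients, `N(0, 10)` on detection — so quasi-separation in sparse
replicates cannot drive the pilot optimum to infinity; standard errors
come from a central-difference numeric Hessian of the penalized
objective. If the pilot fails to converge the sampler falls back to
neutral `N(0,1)` pseudo-priors.

**Marginal likelihood.** For one route-year, `z` and the availability
chain are summed out by a forward recursion over the `2^J` history
space in O(J); exponentials over all histories sum to one for any
parameter set, and the recursion is verified against brute-force
enumeration of all `2 × 2^J` latent configurations to 1e-10.

## Sampler

Blocked Gibbs:

- each sweep opens with collapsed moves on the availability/detection
  block `(α₀, π_t, θ, θ', eta-scale)` against the latent-marginalised
  likelihood: slice sampling along the scalar coordinates, along
  randomly-sloped "ridge" directions (detection up, availability down)
  and along isotropic signed random directions — the trade between a
  persistent availability chain thinned by mid detection and a weakly
  persistent chain seen with high detection moves `θ` and `θ'` in
  opposite directions, which fixed-sign slopes cannot cross — plus an
  exact translation move between `α₀` and the observer-effect
  mean and a scale-group move jointly rescaling `(η, σ²_obs)`. Without
  these, `p → 1` makes the imputed availability equal the history — a
  nearly absorbing state for the conditional blocks, because detection
  then sees only successes. The collapsed moves run before the latent
  draw and never read the latents, so the joint posterior is invariant
  (partially collapsed Gibbs);
- `(z, y)` jointly by forward-filter backward-sampling per route-year;
- `π_t, θ, θ'` by conjugate Beta updates given `y`;
- occupancy coefficients `(ν_{1:T}, β_active)` jointly by Pólya-Gamma
  augmentation (one multivariate normal draw over the full random-walk
  path with a banded prior precision);
- detection block `(α, η)` by Pólya-Gamma augmentation;
- indicators `(ω_m, ω_{m²})` by a three-state pairwise update with
  pseudo-prior compensation; the scan is repeated ten times per sweep
  with idle coefficients refreshed from their pseudo-priors between
  scans (their exact conditional), since a switch only happens when the
  current idle draw lands in a high-likelihood region;
- `λ` conjugate Gamma; `log σ_rw`, `log σ_obs` by slice sampling.

Pólya-Gamma `PG(1, z)` variates come from a self-contained
Devroye-type sampler (numba-compiled, explicitly seeded), so draws are
reproducible bit-for-bit given the seed; chains derive their streams
from `numpy.random.SeedSequence` spawning. Convergence is monitored
with split R-hat and ESS (via ArviZ) on all scalar parameters and a
subset of `ν` coefficients.

The full transition kernel is validated with a successive-conditional
(joint-distribution) test: alternately drawing data given parameters
and one Gibbs sweep given data must leave the prior-times-likelihood
joint invariant, which is checked against the known prior marginals.

## Prediction and range indices

Posterior occupancy surfaces are evaluated on a raster grid restricted
to a convex hull of routes with detections, buffered by 2° (shapely);
cells outside the spline's training extent are flagged. Index series,
computed per posterior draw and year: proportion of area occupied
(mean `ψ` over cells), occupancy-weighted mean breeding latitude, and
range limits defined as the latitudes bounding `1 − 2·tail_mass` of
the occupancy mass (cumulative mass over sorted unique latitudes,
inverted with a monotone PCHIP interpolant anchored at zero mass at
the southernmost cell — ties in latitude are aggregated before
inversion).

## Posterior predictive check

Discrepancy: Freeman–Tukey statistic `Σ (√obs − √exp)²` on the `2^J`
detection-history counts per year, with expected counts computed
exactly from the marginal history probabilities and replicate counts
drawn from the full posterior predictive. The global p-value is
`Pr(FT_rep ≥ FT_obs)` with FT summed over years. A constructed-misfit
dataset whose detected route-years mix two incompatible fixed patterns
(no single Markov availability chain can produce the mixture) yields
p ≈ 0.

## Synthetic-data generator

`simulate_dataset` draws every layer of the model forward: TPRS
surface with random-walk drift, AR(1) climate covariates, Markov
availability, observer histories with geometric tenure (first-year
flags derived from stint starts), missing route-years, wind and
protocol covariates. Named fixtures: `tiny` (3 routes, affine
surface, CLI smoke tests), `selection` (300 routes, 2 active + 8
inert covariates), `shift` (150 routes, 10 years, northward-drifting
surface). Realism limits: covariates are stationary AR(1) rather than
real climate fields; observer effects are exchangeable; routes are
uniform in a rectangle.

## Numerical and design decisions

- **Problem sizes** for the replicated recovery study (150–300 routes,
  6–8 years, 20 replicates) are chosen so the full suite runs on one
  CPU in well under half an hour while leaving enough information to
  identify all parameter blocks.
- **Affine basis fallback**: site sets too small to carry a thin-plate
  smooth (fewer than 4 distinct locations, or `K < 4`) use the exact
  unpenalised plane `{1, lat, lon}`, which is the TPRS null space; the
  CLI selects this automatically.
- **Quarter convention** for bioclim covariates: the climate year runs
  June→May preceding the survey; quarters are the 12 wrapping 3-month
  windows.
- **Pilot simplifications** (static smooth, shared `π`, no observer
  effects) only affect pseudo-prior *locations*, never the posterior
  itself: pseudo-priors cancel exactly in the indicator updates.
- Derived per-chain and per-component seeds are kept below 2³¹.

## Limitations

- Single-species model; no false positives; availability parameters
  `θ, θ'` are shared across routes and years.
- The availability/detection split is identified only by the serial
  signature that independent per-stop thinning leaves on the Markov
  availability runs. When per-stop detection is high (p ≳ 0.7) the
  likelihood is nearly flat along the trade-off between detection and
  availability, and posteriors for `α₀`, `θ'` become very wide;
  simulation studies in the test suite therefore use a persistent
  chain with mid-range detection, where the split is well identified.
- The random-walk surface assumes equally spaced years.
- With one survey year the occupancy surface and availability levels
  are only weakly separated (a near-flat likelihood ridge); multi-year
  data or informative priors are needed for stable separation.
- The prediction grid's climate covariates are taken from the nearest
  route, which is a demonstration device rather than a gridded-climate
  integration.
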