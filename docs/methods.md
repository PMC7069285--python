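# Methods

## Design geometry

One experiment is a fully crossed 3 × 2 × 2 factorial — density (2, 4, 8
individuals per container, always treated as a factor), salinity (fresh,
4 ppt) and population of origin (coastal, inland) — replicated in 6 spatial
blocks: 12 treatment cells × 6 blocks = 72 experimental units, one rearing
container each, with `n_initial` equal to the density level. Time is measured
in days from the start of treatments (the free-feeding larval stage, Gosner
25); day 0 is the first measurement of a weekly grid. The container (not the
individual) is the unit of the growth analysis: the observed response is the
cup-mean total length.

## Growth model

The curve is the standard Gompertz form `Y(t) = S0·exp[(γ/α)(1 − e^(−αt))]`,
i.e. the solution of `dY/dt = γ e^(−αt) Y`. `γ` is the maximum size-specific
growth rate and `α` the exponential decay rate of that rate, both per day;
`S0` is initial size in mm. Implementation notes:

* Evaluation uses `expm1`, so the curve is numerically stable as `α → 0`,
  where it degenerates to exponential growth `S0·e^(γt)`; `α = 0` is handled
  exactly.
* Treatment structure enters through **log-link linear predictors** for γ and
  α with treatment (dummy) coding, reference cell (coastal, fresh, density 2).
  The log link guarantees positive rates for every coefficient vector and
  leaves parameter counts unchanged relative to an identity link; whether the
  original analyses used identity or log scale for these effects is not
  determinable, so the choice is made here for numerical robustness and
  documented. Cell-level rates are always reported on the natural scale.
* The candidate set crosses {L+S+D, L*S+D, L+S*D, L*S*D} on γ and α and adds
  the single no-effects model: 17 parameterizations, each with one shared
  `S0` and one shared residual σ (i.i.d. Gaussian on the cup mean), both
  counted in `k`. Hence the no-effects model has k = 4 and the model with
  additive γ and salinity-by-density α has k = 2 + 5 + 7 = 14. Two rows of
  the published table print df values inconsistent with their own formula
  labels (a duplicated full/full row and a duplicated additive/additive row);
  the formula-based count is used throughout.
* Maximum likelihood uses multi-start L-BFGS-B with an analytic gradient
  (chain rule through the curve and both log links). Starting values are
  method-of-moments: `S0` from the first-measurement mean, the asymptote from
  the last-week mean, α from a coarse half-life grid {0.02, 0.05, 0.10}/day,
  with seeded Gaussian perturbations for the remaining restarts (10 by
  default; heavy simulation studies in the test-suite use 3, which pilot runs
  showed recover the same optimum as independent restart seeds to < 1e-6).
  Reference-cell rates are bounded to [1e-4, 5]/day, other coefficients to
  ±6 on the log scale. Non-convergent fits are retained in the model table
  and flagged, never dropped.
* AICc uses n = the number of cup-mean growth observations pooled over units
  and weeks. Ranking ties are broken by enumeration order (γ-major over the
  four structures, null last).

## Endpoint GLMMs

* **Responses.** Survival: survivors out of `n_initial`, aggregated per
  container (the response grain is not recoverable from the source analyses;
  aggregation is the natural container-level choice). Age at metamorphosis:
  integer days, per surviving individual, Poisson with log link (a dispersion
  diagnostic is printed as a warning when Pearson χ²/df > 1.5, but no
  correction is applied). Length at metamorphosis: log-transformed mm, per
  surviving individual, Gaussian.
* **Random effect.** The 6 spatial blocks enter as a Gaussian random
  intercept on each family's link scale. A cup-level random effect would be
  confounded with the experimental unit and is not used.
* **Marginal likelihood.** Block intercepts are integrated out by a Laplace
  approximation: the per-block mode is found by damped Newton iterations
  (the one-dimensional objective is concave for the canonical links), then
  `ℓ_j = g_j(b̂) − b̂²/(2σ_b²) − ½log(σ_b²·(−h''(b̂)))`. With only 6 balanced
  grouping levels this single-quadrature-point approximation is adequate; it
  is exact for the Gaussian family, which is evaluated in closed form via
  Sherman–Morrison within blocks and cross-checked in the tests against a
  dense multivariate-normal density. σ_b is optimized on its natural scale
  with a lower bound of exactly 0, so boundary fits are representable and
  flagged; σ_b = 0 reduces the likelihood to the corresponding GLM exactly
  (verified against statsmodels).
* **Inference.** All fits are ML (not REML), so likelihood-ratio tests on
  nested fixed-effect structures are valid. Backward elimination tests the
  3-way interaction first (retained ⇒ stop); otherwise the least significant
  removable 2-way term with p ≥ α (default α = 0.05) is dropped and the model
  refitted until all retained terms are significant. Each main effect is then
  reported as an LRT against the final model with that effect and any
  retained interaction containing it removed. Complete separation in the
  binomial family (degenerate responses or diverging coefficients) is
  flagged, and fitted coefficients are bounded to keep the optimizer finite.
* **Cell means.** Per-cell fitted means use the final model at the random-
  effect mode 0, with delta-method standard errors from a central-difference
  Hessian of the marginal negative log-likelihood.

## Synthetic-data generator

The generator draws what the analyses assume: Gompertz cup-mean growth with
i.i.d. Gaussian noise; binomial survival; Poisson metamorphosis day and
log-normal metamorphic length for survivors (the configured cell value is
the median, i.e. exp of the log-scale mean); independent per-endpoint block
intercepts with a common sd on each link scale. Deaths are assigned a
uniform random day over the unit's larval period (the real sampling records
daily mortality, but its time structure is not specified); growth
observations stop once a container is empty. One `numpy` Generator seeded
from `SimulationConfig.seed` drives everything, so identical configs give
bitwise-identical datasets.

**Default configuration** (the study conditions the pipeline demonstrates):
S0 = 6 mm, σ_resid = 0.5 mm, block_sd = 0.1, weekly measurements to day 77.
Survival 0.95/0.85/0.703 by density (a 26% relative drop from low to high
density); metamorphosis at 45/58/74 days by density plus 4 days for the
salt × high-density cell (~66% older at high density); median metamorphic
length 37.7 mm coastal vs 36.0 mm inland (1.7 mm location effect) with a
±0.5 mm density spread; γ = 0.16/0.10/0.056 per day by density (a 2.86-fold
low-to-high ratio) with ×0.95 inland and ×0.95 salt multipliers (log-additive
⇒ an additive structure on log γ); α = 0.080/0.045/0.024 per day with salt
multipliers 1.0/1.15/1.25 by density and ×0.97 inland (⇒ location + a
salinity-by-density interaction on log α — the structure the top-ranked
growth model recovers).

What the generator does **not** emulate: individual-level growth variation
within a container (only the cup mean is modeled), correlation between an
individual's growth and its endpoint values (metamorph lengths are drawn from
the endpoint model, not read off the growth curve), time-varying salinity or
husbandry effects, overdispersion in metamorphosis day, or non-Gaussian
block effects. Passing tests therefore certify the estimators and the
selection machinery under the assumed data-generating process, not the fit of
those assumptions to any real experiment.

## Simulation-study designs in the test suite

* **Parameter recovery** uses 72 units × 8 weekly points, σ = 0.5 mm, and a
  strong-effects configuration whose α values (0.06–0.29/day) all produce
  visible curvature inside the 8-week window, so both rates are well
  identified in every cell; over 100 replicates the cell-wise mean estimates
  are required to sit within 3 Monte-Carlo standard errors of truth.
* **Model-selection consistency** requires the generating parameterization to
  win rank 1 in ≥ 90% of 50 replicates. AICc retains a positive probability
  of preferring a spuriously extended nested model — asymptotically
  P(χ²₁ > 2) ≈ 16% per one-parameter extension, independent of effect size —
  so consistency at that level is only attainable when the small-sample
  correction term is large, i.e. few observations per parameter. The study
  is therefore designed at n = 36: one block (12 units, one per cell) measured
  at days 0, 14 and 35 (initial size, mid-rise, near-asymptote), which raises
  the effective penalty for one extra parameter to ≈ 6 AICc units. Separating
  *which* rate carries the salinity-by-density interaction (an equal-k
  competitor places it on γ instead of α) is a curve-shape question, so this
  design lowers cup-mean noise to 0.25 mm and strengthens the interaction
  (salt × 1.8 at medium, × 3.0 at high density). Pilot runs of this design
  put the per-replicate success probability near 0.95.
* **LRT calibration** simulates 500 no-effect experiments (common survival
  0.8, block sd 0.2) and requires the density-effect LRT to reject at
  p < 0.05 between 3% and 8% of the time — a band that absorbs both binomial
  Monte-Carlo error and the small Laplace/χ² approximation error at these
  trial counts.

## Known limitations

* The Laplace approximation is not replaced by adaptive quadrature; with
  binomial denominators of 2–8 its likelihood values can deviate slightly
  from a fully integrated likelihood (the calibration test bounds the
  practical consequence).
* The per-area density figures sometimes quoted for this design
  (22/44/88 per m²) are not derivable from the stated 11 cm container
  diameter and are therefore reported nowhere as computed quantities.
* Growth and endpoint simulations are linked only through survival (growth
  series stop when a container empties), not through shared individual-level
  latent variation.
* The elimination procedure tests terms marginally at each step; it does not
  explore the full model lattice, mirroring standard sequential LRT practice
  rather than exhaustive model averaging.
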