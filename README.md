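# larvalfit

Growth-curve model selection and mixed-model endpoint analysis for factorial
larval-rearing experiments.

`larvalfit` implements the analysis pipeline for a classic experimental-ecology
design: amphibian larvae (e.g. *Hyla cinerea* tadpoles) reared at three
densities (2, 4 or 8 per container) crossed with two salinities (fresh water,
4 ppt) and two populations of origin (coastal, inland), replicated in six
spatial blocks — 72 experimental units. The package is aimed at ecologists who
want to (1) compare treatment-structured growth-curve parameterizations by
information criteria and (2) test treatment effects on metamorphosis endpoints
with block random effects, plus a synthetic-data generator so the whole
pipeline is testable without any external data.

## The models

**Growth.** Container-mean total length follows a Gompertz curve

```
Y(t) = S0 · exp[(γ/α) · (1 − e^(−αt))]
```

with `S0` the initial size (mm) at the start of treatments (Gosner stage 25),
`γ` (1/day) the maximum size-specific growth rate (`dY/dt = γ e^(−αt) Y`) and
`α` (1/day) the exponential decay rate of that size-specific rate; the
asymptote is `S0·exp(γ/α)`. Treatments enter through linear predictors for
log γ and log α built from Location, Salinity and Density (a 3-level factor)
under treatment coding. Crossing four effect structures
{L+S+D, L*S+D, L+S*D, L*S*D} on γ and α, plus a single no-effects model,
gives 17 candidate parameterizations, every one sharing a single `S0` and
residual σ. Each is fitted by maximum likelihood (multi-start L-BFGS-B with
analytic gradients) and ranked by AICc,

```
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),     w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)
```

with Akaike weights `w_i` quantifying relative support.

**Endpoints.** Survival to metamorphosis (binomial, logit link, aggregated
per container), age at metamorphosis (Poisson, log link, per individual) and
total length at metamorphosis (Gaussian on the log response) are fitted as
GLMMs with Location, Salinity and Density as fixed effects and the spatial
block as a Gaussian random intercept, integrated out by a Laplace
approximation (exact for the Gaussian family). Fixed-effect structure is
reduced by backward elimination with likelihood-ratio tests, and each main
effect is reported as a chi-square test against the model lacking it.

## Worked example

```bash
larvalfit run-all --seed 1 --out demo --restarts 3
```

simulates one experiment under the default configuration (which encodes the
qualitative effect structure the design is built to detect: a ~26% survival
drop at high density, a salinity-by-density interaction on the decay of
growth, a ~1.7 mm coastal advantage in metamorphic length), fits all 17
growth parameterizations, ranks them, and runs the three endpoint analyses:

```
Gompertz growth model comparison (AICc)

S0  gamma                             alpha                              Rank    dAICc   df   Weight
1   Location + Salinity + Density     Location + Salinity * Density         1      0.0   14    0.501
1   Location * Salinity + Density     Location + Salinity * Density         2      1.5   15    0.242
1   Location + Salinity + Density     Location * Salinity * Density         3      3.1   19    0.107
...
1   1                                 1                                    17   3462.8    4    0.000

Best-supported model: gamma = Location + Salinity + Density; alpha = Location + Salinity * Density (df=14, weight=0.501)

Endpoint analyses (likelihood-ratio tests)

endpoint                  term            chisq  df         p
survival                  Location         3.79   1    0.0514
survival                  Salinity         0.70   1    0.4026
survival                  Density         14.49   2    0.0007
age_at_metamorphosis      Location         0.36   1    0.5477
age_at_metamorphosis      Salinity         8.94   3    0.0301
age_at_metamorphosis      Density        656.04   4    0.0000
length_at_metamorphosis   Location        48.73   1    0.0000
length_at_metamorphosis   Salinity         0.05   1    0.8165
length_at_metamorphosis   Density         11.98   2    0.0025
```

Reading this output: the top-ranked growth model has additive
location/salinity/density effects on γ but a salinity × density interaction
on α — the generating structure — with Akaike weight 0.50; `df` is the
parameter count (here 14 = S0 + σ + 5 γ-coefficients + 7 α-coefficients).
The endpoint table shows density dominating survival and age at
metamorphosis, and location (population of origin) dominating metamorphic
length, matching what was simulated. The run directory also contains the
three dataset CSVs, `model_table.csv`, `fits.json`, `endpoint_report.json`
(per-cell fitted means with standard errors, elimination traces) and a
`manifest.json` with the seed and config hash; rerunning with the same seed
reproduces every file byte-for-byte.

The subcommands `simulate`, `fit-growth`, `select` and `endpoints` expose the
same stages individually; see `larvalfit --help`.

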