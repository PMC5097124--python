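# Methods

## Visitation model

The response is the natural log of average annual tourist visits at a
protected area (PA). Predictors, on the analysis scale: log PA area,
elephant density (km⁻², untransformed), forest indicator, density × forest
interaction, lion presence, natural attractiveness (1–5 score, raw), log
nearby human population, log accessibility (minutes from the nearest large
city), log national income (PPP). Density enters untransformed because the
reported effect sizes are per-unit-density semi-elasticities
(100 × (e^β − 1) percent per km⁻²) and marginal-visit calculations scale the
per-unit effect linearly in the density change; both readings require a
linear density term.

Elephant density is observed with error. For each elephant-holding PA the
census supplies a population mean and one of three uncertainty forms:

* **sd form** — the population sd is reported; the density observation sd is
  pop sd / censused area.
* **range form** — a (lo, hi) range is read as a central 95% interval of a
  normal: mean = midpoint, sd = (hi − lo)/(2 × 1.959964).
* **none** — the sd is missing and is imputed *inside* the model: the
  missing population sd is a parameter with prior
  N(192 + 0.122 × mean, τ²) truncated to positive values. The line's
  residual scale τ is estimated from the records that do report an sd
  (sample sd of their residuals about the line, floored at 10; default 100
  when fewer than three such records exist) and can be configured.

The true density d_i is latent with likelihood contribution
N(d̂_i; d_i, s_i²) and an (improper) flat prior on [0, ∞). PAs with a
reported sd of exactly zero have their density pinned at the census value;
PAs without elephants enter with density fixed at 0 and no observation
model. This is the *functional* errors-in-variables treatment — each latent
density gets its own observation-centred distribution rather than a shared
population distribution — which matches how census uncertainty is reported
and keeps every record's uncertainty record-specific.

### Priors and sampling

Coefficients have vague N(0, 10²) priors on an internally standardized scale
(continuous non-latent columns centred and scaled; binaries, the latent
density and the interaction stay raw); draws are mapped back to the analysis
scale before reporting. The residual scale σ has a half-N(0, 5) prior.

Sampling is Metropolis-within-Gibbs:

1. coefficients — conjugate multivariate-normal update given latents and σ;
2. σ — univariate slice sampling on ln σ (stepping-out + shrinkage, w=0.5);
3. latent densities — the full conditional is a product of two normals
   (visits likelihood × census observation), sampled exactly as a
   truncated-at-zero normal, vectorized across records;
4. imputed population sds — log-scale random-walk Metropolis against the
   mean–sd line, with the proposal scale tuned toward ~40% acceptance in
   warmup blocks of 50 iterations (fixed thereafter).

Chains are seeded from a `SeedSequence` spawn of the configuration seed, so
identical configurations reproduce draw matrices exactly. Convergence is
assessed by split R-hat ≤ 1.01 and a minimum effective sample size for every
sampled parameter (ArviZ implementations). At the desk-scale default used by
the tests (2–4 chains × a few hundred iterations) the regression
coefficients and σ pass easily, but some weakly identified per-record
parameters — latent densities of tiny populations whose observation sd is
itself imputed — need the study-scale configuration (4 chains ×
25,000 warmup + 25,000 sampling, available via `paper_scale_config`) to
clear the same bar; the convergence report states this honestly rather than
relaxing the threshold.

### Prediction, counterfactual

Posterior-predictive visits at density d hold every other covariate at its
fit-data mean (on the transformed scale); the forest flag can be overridden
per query so the interaction uses the queried PA's habitat. The poaching
counterfactual compares median predicted visits at the census density with
the density scaled by (1 − annual decline rate), the decline rate being an
upstream-derived annual proportional loss to illegal killing. Both arms use
census mean / censused area as the baseline density; the visit loss is the
difference of medians, floored at zero (a log note records any flooring).
One year of poaching is the horizon throughout.

## Valuation

Per-visit direct spending is exponential with the maximum-likelihood rate
λ = 1/mean fitted to literature estimates; the local-economy total-impact
multiplier is Gaussian (sample mean/sd) truncated at 1 when sampled, since a
total-impact multiplier below 1 would imply negative indirect spending. Per
replicate and per PA, independently: direct = visit loss × spend draw,
indirect = direct × (multiplier − 1), total = direct + indirect. Draws are
not shared across PAs. Summaries are means and 2.5/97.5 percentiles over
(default) 100,000 replicates. A closed-form oracle
(E[direct] = Σ loss × mean spend; truncated-normal mean computed
analytically) provides an independent check; tests require agreement within
3 Monte Carlo standard errors at 10⁵ draws. Regional "total benefit"
summaries are means of per-replicate totals; a median-based total would not
equal the sum of the direct and indirect columns for skewed distributions,
which is why means are reported.

## Cost model and ROI

The only calibration facts used are: population change depends on per-km²
conservation spending, and zero decline of large (>1,000) populations costs
$215 km⁻² in 1981 USD = $565 km⁻² in 2016 USD (inflation is a configured
scalar 565/215, not a CPI lookup). These are embedded in a one-parameter
log-spend growth model g(s) = b(ln s − ln 565) anchored exactly at the
benchmark; b defaults to 0.05 per unit ln-spend and is configurable. Implied
current spend at a PA declining at rate r is 565·e^(−r/b) (or the record's
reported spending when present); the annual shortfall is
max(0, 565 − current) × PA area, restricted to PAs above the 1,000-elephant
threshold. Regional ROI = 100 × (benefit − cost)/cost uses the package's own
simulated mean benefits at the same large-population PAs.

## Synthetic-data generator

The generator emulates the study design, not African geography: 216
elephant-holding PAs plus 54 elephant-free PAs with visitor data (164 PAs
with visits, 110 of them with elephants); uncertainty forms assigned at
deterministic counts 43% sd / 12% range / 45% missing; ~58 populations above
1,000 elephants. Log visits come from the model above using the latent true
density, with residual sd 1.2 and a default intercept of 7.3 chosen once so
median annual visits land near the observed order of magnitude (~2,000).
Census means are noisy observations of the true population with sd from the
192 + 0.122 × mean line plus N(0, 60) jitter; the reported sd/range reflects
the noise actually applied, so the fit is correctly specified (an
`obs_noise_scale` knob scales both for attenuation experiments).

Covariates: log-uniform area (10–10⁴ km²), nearby population (10³–10⁷),
accessibility (30–3,000 min), national income (10³–3×10⁴); Bernoulli forest
(p=0.25) and lion (p=0.6); uniform integer attractiveness; annual poaching
decline rates uniform on (0, 0.12). Density is coupled to population size
as in real censuses: large populations draw density U(0.3, 2) km⁻² with
censused area = pop/density, while small populations draw a censused area
log-uniform on (500, 10⁴) km² so density = pop/area is low. An independent
density ~ U(0, 2) for all populations would give small herds implausibly
tiny census zones and density-scale observation noise larger than the whole
density range, destroying identification of the density effect for any
estimator — the coupling keeps the synthetic study informative about the
parameter it is meant to recover. Latent truths are emitted in a separate
companion table so the PA table itself has exactly the real-data schema.

The single-site panel generator produces a multi-decade series with smooth
exponential area/GDP growth and an upward-trending, year-to-year-variable
density, driving log visits through the reduced model (intercept, log area,
log GDP, density; defaults β_density = 0.67, residual sd 0.35).

What passing tests on these data do *not* show: anything about real
covariate marginals or their correlations, spatial structure, temporal
drift between census rounds and visitation records, or reporting biases in
visitor counts — the generator is deliberately exchangeable across PAs
except through its covariates.

## Problem sizes and numerical choices

Tests run the sampler at 2–4 chains × 150–500 warmup/sampling iterations and
the valuation at 10³–10⁵ draws; the calibration test uses 50 replicates of
the full 270-record study at 2 × (300 + 300). The study-scale configuration
(4 × 25k + 25k, 10⁵ draws) is exposed through `paper_scale_config` and the
CLI's `--mcmc-scale paper`. Degenerate inputs: visits ≤ 0 refuse to
log-transform with the PA named; lo > hi ranges are rejected; a collinear
within-site design raises before sampling; zero visit losses yield exactly
zero monetary losses. CSV round-trips are bit-stable (floats written as
shortest exact decimals, parsed with round-trip precision).

## Known limitations

* The functional errors-in-variables treatment does not borrow strength
  across PAs; densities of small, noisily censused populations are weakly
  identified and mix slowly, which is visible in their R-hat at short chains.
* The growth–spending model is a deliberate single-parameter anchor, not a
  refit of the underlying 1980s cross-country regression; ROI figures should
  be read as conditional on its slope.
* Regional ROI is computed from the package's simulated mean benefits and
  shortfalls; alternative estimators (medians, draws-level ROI intervals)
  would give different point values for skewed distributions.
* The valuation treats visit losses as fixed per PA while spending draws
  vary; posterior uncertainty in the visit losses themselves propagates only
  through the median predictions, not the full predictive distribution.
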