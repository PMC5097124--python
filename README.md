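# elevisits

Bayesian modelling of how elephant abundance drives tourism to African
protected areas (PAs), and what poaching therefore costs in lost visitor
spending.

`elevisits` is a library for conservation economists and ecologists who want
to (1) estimate the effect of elephant density on PA visitation while
honouring the measurement uncertainty of elephant censuses, (2) predict the
annual tourist visits lost to poaching-driven density declines, (3) monetize
those losses by Monte Carlo over per-visit spending and local-economy
multiplier distributions, and (4) compare them with the anti-poaching
spending shortfall needed to stabilize large elephant populations. A
synthetic-data generator reproduces the statistical structure of the study
design (164 PAs with visitor counts, 216 elephant populations, mixed
uncertainty reporting), so the entire pipeline is testable without any data
downloads.

## The model

Average annual visits \(V_i\) at PA \(i\) follow a log-linear regression

\[
\ln V_i = \beta_0 + \beta_d\, d_i + \beta_{df}\, d_i f_i + \mathbf{x}_i^\top
\boldsymbol\gamma + \varepsilon_i,\qquad \varepsilon_i \sim N(0, \sigma^2),
\]

where \(d_i\) is elephant density (km⁻²), \(f_i\) the forest indicator, and
\(\mathbf{x}_i\) the remaining covariates (log area, lion presence, natural
attractiveness 1–5, log nearby population, log accessibility, log national
income). Density is an **errors-in-variables** predictor: the census gives a
population mean and (for 55% of populations) an sd or a range, and the model
treats the true density as latent with

\[
\hat d_i \sim N(d_i,\, s_i^2), \qquad
\hat d_i = \frac{\text{pop mean}_i}{\text{censused area}_i},\quad
s_i = \frac{\text{pop sd}_i}{\text{censused area}_i},
\]

ranges converted via midpoint/95%-interval reading, and missing population
sds imputed inside the model from the empirical line
\(\mathrm{sd} = 192 + 0.122 \times \mathrm{mean}\). The joint posterior is
sampled by Metropolis-within-Gibbs (conjugate coefficient updates, slice
sampling for \(\sigma\), truncated-normal updates for latent densities,
adaptive random-walk Metropolis for imputed sds), with split R-hat and ESS
diagnostics from ArviZ.

Downstream, the poaching counterfactual reduces each density by its annual
illegal-killing decline rate, takes the difference of posterior-predictive
median visits, and the valuation multiplies each PA's visit loss by
exponential spend draws and truncated-Gaussian multiplier draws, 100,000
times. The cost model is anchored at the zero-decline benchmark of
\$565 km⁻² (USD 2016; \$215 in 1981 dollars): regional rate of return is
\(100 \times (\text{benefits} - \text{costs}) / \text{costs}\).

## Worked example

```python
from elevisits import (SyntheticParams, effect_size_percent,
                       fit_visitation_model, generate_pa_table,
                       test_scale_config)

records, truth = generate_pa_table(SyntheticParams(seed=1))
fit = fit_visitation_model(records, test_scale_config(seed=1))
print(fit.summary().round(2).head(3).to_string(index=False))
beta = float(fit.coefficient("elephant_density").mean())
print(f"density effect: +{effect_size_percent(beta):.0f}% visits per km^-2")
```

prints

```
       parameter  mean   sd  q2.5  q97.5    ess  rhat
       intercept  7.38 1.09  5.35   9.52 799.99   1.0
        log_area -0.32 0.05 -0.41  -0.23 703.98   1.0
elephant_density  1.33 0.21  0.94   1.78 648.14   1.0
density effect: +280% visits per km^-2
```

The generator's true density coefficient is 1.55 — the 95% credible interval
(0.94, 1.78) covers it — and `effect_size_percent` converts a log-linear
coefficient into the percent change in visits per unit density
(100 × (e^β − 1); at β = 1.55 that is 371%). The `examples/` directory has
one narrative script per capability: model fitting, the poaching
counterfactual, Monte Carlo valuation, the cost/ROI assessment and the
single-site time-series check. A thin CLI wraps the same stages
(`elevisits simulate | fit | counterfactual | value | roi | run-all`).

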