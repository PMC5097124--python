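"""Bayesian errors-in-variables regression of log annual PA visits.

The response is the natural log of average annual tourist visits. Elephant
density (population mean / censused area, km^-2) enters as a latent predictor
observed with record-specific normal noise; population sds missing from the
census are imputed inside the model from the empirical linear mean-sd
relation. Remaining covariates are ordinary fixed predictors, most of them
log-transformed.

The joint posterior over coefficients, the residual scale, latent densities
and imputed sds is sampled by Metropolis-within-Gibbs:

* coefficients — conjugate multivariate-normal update (vague normal prior on
  internally standardized columns);
* residual scale sigma — univariate slice sampling under a half-normal prior;
* latent densities — conjugate normal (visits likelihood x census observation
  model) truncated at zero;
* imputed population sds — log-scale random-walk Metropolis against the
  mean-sd line.

Split R-hat and effective sample sizes come from arviz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .config import Z_975, ImputationConfig, PipelineConfig
from .io import PARecord

#: Design columns of the full visitation model, in reporting order.
FULL_PREDICTORS = (
    "intercept",
    "log_area",
    "elephant_density",
    "forest",
    "density_forest",
    "lion",
    "attractiveness",
    "log_nearby_pop",
    "log_accessibility",
    "log_country_ppp",
)
_DENSITY = FULL_PREDICTORS.index("elephant_density")
_INTERACTION = FULL_PREDICTORS.index("density_forest")
_FOREST = FULL_PREDICTORS.index("forest")
#: Continuous non-latent columns that are standardized inside the sampler.
_STANDARDIZED = ("log_area", "attractiveness", "log_nearby_pop",
                 "log_accessibility", "log_country_ppp")


class TransformError(ValueError):
    """A record could not be placed on the design scale (e.g. visits <= 0)."""


class FitError(RuntimeError):
    """The sampler could not produce a fit (degenerate design, failure)."""


def range_to_normal(lo: float, hi: float) -> tuple[float, float]:
    """Convert a population range to a normal (mean, sd).

    The range midpoint is the mean and the endpoints are read as a central
    95% interval, so sd = (hi - lo) / (2 * z_0.975).
    """
    if lo > hi:
        raise ValueError(f"range lower bound {lo} exceeds upper bound {hi}")
    return (lo + hi) / 2.0, (hi - lo) / (2.0 * Z_975)


def impute_population_sd(mean: float, params: ImputationConfig | None = None) -> float:
    """Point imputation of a missing population sd from the mean-sd line.

    Inside the sampler the missing sd is a parameter centred on this line;
    this function returns the line itself, sd = intercept + slope * mean.
    """
    if mean < 0:
        raise ValueError("population mean must be nonnegative")
    p = params or ImputationConfig()
    return p.intercept + p.slope * mean


def effect_size_percent(beta: float) -> float:
    """Percent change in visits per unit predictor in a log-linear model:
    100 * (exp(beta) - 1)."""
    return 100.0 * (math.exp(beta) - 1.0)


def marginal_visits(median_visits: float, beta: float, delta_density: float) -> float:
    """Additional annual visits at a baseline visit count for a density change,
    scaling the per-unit semi-elasticity linearly:
    median_visits * delta_density * (exp(beta) - 1)."""
    if median_visits <= 0:
        raise ValueError("median_visits must be positive")
    return median_visits * delta_density * (math.exp(beta) - 1.0)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Analysis-scale design for the visitation model.

    X holds observed densities as a plug-in for the latent column; the
    sampler overwrites the latent entries each iteration.
    """

    names: tuple[str, ...]
    y: np.ndarray                 # (n,) log visits
    X: np.ndarray                 # (n, p) analysis scale
    forest: np.ndarray            # (n,) 0/1
    pa_ids: list[str]
    latent_idx: np.ndarray        # rows whose density is latent
    d_obs: np.ndarray             # (n_lat,) observed density
    s_obs: np.ndarray             # (n_lat,) density-scale obs sd (NaN if missing)
    uncertainty_form: list[str]   # per latent row: "sd" | "range" | "none"
    pop_mean: np.ndarray          # (n_lat,) population mean
    censused_area: np.ndarray     # (n_lat,)


def _density_observation(rec: PARecord) -> tuple[float, float]:
    """(density mean, density sd) for a record with elephants; sd is NaN when
    the population sd is missing (range-form converted first)."""
    area = rec.censused_area_km2
    if rec.uncertainty_form == "sd":
        return rec.elephant_pop_mean / area, rec.elephant_pop_sd / area
    if rec.uncertainty_form == "range":
        mean, sd = range_to_normal(rec.elephant_pop_lo, rec.elephant_pop_hi)
        return mean / area, sd / area
    return rec.elephant_pop_mean / area, float("nan")


def build_design(records: Sequence[PARecord]) -> Design:
    """Assemble response and design matrix from records with observed visits.

    Raises :class:`TransformError` naming the pa_id when visits cannot be
    log-transformed.
    """
    n = len(records)
    y = np.empty(n)
    X = np.empty((n, len(FULL_PREDICTORS)))
    forest = np.empty(n)
    latent_rows, d_obs, s_obs, forms, pops, areas = [], [], [], [], [], []
    for i, rec in enumerate(records):
        if rec.visits is None or rec.visits <= 0:
            raise TransformError(f"pa_id={rec.pa_id!r}: visits must be positive to log-transform")
        y[i] = math.log(rec.visits)
        dens = rec.observed_density
        X[i] = (
            1.0,
            math.log(rec.area_km2),
            dens,
            float(rec.forest),
            dens * float(rec.forest),
            float(rec.lion),
            float(rec.natural_attractiveness),
            math.log(rec.nearby_population),
            math.log(rec.accessibility_minutes),
            math.log(rec.country_ppp),
        )
        forest[i] = float(rec.forest)
        if rec.has_elephants:
            dmean, dsd = _density_observation(rec)
            if math.isnan(dsd) or dsd > 0:
                latent_rows.append(i)
                d_obs.append(dmean)
                s_obs.append(dsd)
                forms.append(rec.uncertainty_form)
                pops.append(rec.elephant_pop_mean)
                areas.append(rec.censused_area_km2)
            # a reported sd of exactly 0 pins the density at its census value
    return Design(
        names=FULL_PREDICTORS,
        y=y,
        X=X,
        forest=forest,
        pa_ids=[r.pa_id for r in records],
        latent_idx=np.asarray(latent_rows, dtype=int),
        d_obs=np.asarray(d_obs),
        s_obs=np.asarray(s_obs),
        uncertainty_form=forms,
        pop_mean=np.asarray(pops),
        censused_area=np.asarray(areas),
    )


# ---------------------------------------------------------------------------
# posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """Posterior draws for the visitation model, on the analysis scale."""

    names: tuple[str, ...]
    beta: np.ndarray               # (chains, draws, p)
    sigma: np.ndarray              # (chains, draws)
    latent_density: np.ndarray     # (chains, draws, n_lat)
    imputed_sd: np.ndarray         # (chains, draws, n_miss)
    latent_pa_ids: list[str]
    imputed_pa_ids: list[str]
    covariate_means: np.ndarray    # (p,) analysis-scale column means of the fit data
    seed: int

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.beta.shape[1]

    def beta_flat(self) -> np.ndarray:
        """(chains*draws, p) coefficient draws."""
        return self.beta.reshape(-1, self.beta.shape[-1])

    def coefficient(self, name: str) -> np.ndarray:
        return self.beta_flat()[:, self.names.index(name)]

    def to_inference_data(self) -> az.InferenceData:
        posterior = {f"beta_{n}": self.beta[:, :, k] for k, n in enumerate(self.names)}
        posterior["sigma"] = self.sigma
        for j, pa in enumerate(self.latent_pa_ids):
            posterior[f"density_{pa}"] = self.latent_density[:, :, j]
        for j, pa in enumerate(self.imputed_pa_ids):
            posterior[f"pop_sd_{pa}"] = self.imputed_sd[:, :, j]
        return az.from_dict(posterior=posterior)

    def to_tidy(self) -> pd.DataFrame:
        """Draws as a tidy (chain, iteration, parameter, value) table."""
        rows = []
        c, d, p = self.beta.shape
        chains = np.repeat(np.arange(c), d)
        iters = np.tile(np.arange(d), c)
        for k, name in enumerate(self.names):
            rows.append(pd.DataFrame({
                "chain": chains, "iteration": iters,
                "parameter": f"beta_{name}", "value": self.beta[:, :, k].ravel(),
            }))
        rows.append(pd.DataFrame({
            "chain": chains, "iteration": iters,
            "parameter": "sigma", "value": self.sigma.ravel(),
        }))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Coefficient summary in reporting layout: mean, sd, 2.5%, 97.5%,
        effective samples, R-hat (plus the residual scale)."""
        idata = az.from_dict(posterior={
            **{f"beta_{n}": self.beta[:, :, k] for k, n in enumerate(self.names)},
            "sigma": self.sigma,
        })
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rows = []
        for k, name in enumerate(self.names):
            draws = self.beta[:, :, k].ravel()
            rows.append({
                "parameter": name,
                "mean": draws.mean(),
                "sd": draws.std(ddof=1),
                "q2.5": np.quantile(draws, 0.025),
                "q97.5": np.quantile(draws, 0.975),
                "ess": float(ess[f"beta_{name}"].values),
                "rhat": float(rhat[f"beta_{name}"].values),
            })
        sig = self.sigma.ravel()
        rows.append({
            "parameter": "sigma", "mean": sig.mean(), "sd": sig.std(ddof=1),
            "q2.5": np.quantile(sig, 0.025), "q97.5": np.quantile(sig, 0.975),
            "ess": float(ess["sigma"].values), "rhat": float(rhat["sigma"].values),
        })
        return pd.DataFrame(rows)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame = field(repr=False)   # parameter, rhat, ess
    rhat_max: float
    ess_min: float

    @property
    def passed(self) -> bool:
        ok = (self.table["rhat"] <= self.rhat_max) & (self.table["ess"] >= self.ess_min)
        return bool(ok.all())

    def to_dict(self) -> dict:
        return {
            "pass": self.passed,
            "rhat_max": self.rhat_max,
            "ess_min": self.ess_min,
            "worst_rhat": float(self.table["rhat"].max()),
            "min_ess": float(self.table["ess"].min()),
            "parameters": self.table.to_dict(orient="records"),
        }


def check_convergence(fit: PosteriorFit, config: PipelineConfig) -> ConvergenceReport:
    """Split R-hat and bulk ESS for every sampled parameter."""
    if fit.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    idata = fit.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = [{"parameter": name, "rhat": float(rhat[name].values),
             "ess": float(ess[name].values)} for name in rhat.data_vars]
    return ConvergenceReport(
        table=pd.DataFrame(rows),
        rhat_max=config.convergence.rhat_max,
        ess_min=config.convergence.ess_min,
    )


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _slice_sample_log(x0: float, logf, rng: np.random.Generator,
                      w: float = 0.5, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    level = logf(x0) - rng.exponential()
    lo = x0 - rng.uniform(0, w)
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= level:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= level:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > level:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _truncated_normal(rng: np.random.Generator, mu: np.ndarray,
                      sd: np.ndarray) -> np.ndarray:
    """Draws from N(mu, sd^2) truncated to [0, inf), vectorized."""
    a = (0.0 - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)


def _run_chain(rng, y, Xw, dens_col, inter_col, forest, lat, d_obs, s_known,
               miss, pop_mean_miss, area_miss, tau, imput, coef_scale,
               sigma_scale, warmup, iters):
    """One MCMC chain on the working (standardized) scale.

    lat indexes rows with a latent density; miss indexes *within lat* the
    records whose population sd is itself imputed. Returns draws after warmup.
    """
    n, p = Xw.shape
    n_lat, n_miss = len(lat), len(miss)
    eye = np.eye(p)

    # --- initial state, overdispersed across chains ---
    d = np.clip(d_obs + 0.05 * rng.standard_normal(n_lat), 0.0, None) if n_lat else np.empty(0)
    sd_pop = np.empty(0)
    s = s_known.copy()
    if n_miss:
        line = imput.intercept + imput.slope * pop_mean_miss
        sd_pop = np.clip(line * np.exp(0.2 * rng.standard_normal(n_miss)), 1.0, None)
        s[miss] = sd_pop / area_miss
    if n_lat:
        Xw[lat, dens_col] = d
        Xw[lat, inter_col] = d * forest[lat]
    beta = np.linalg.solve(Xw.T @ Xw + eye, Xw.T @ y)
    beta += 0.1 * rng.standard_normal(p)
    resid = y - Xw @ beta
    sigma = max(float(np.sqrt(resid @ resid / max(n - p, 1))), 0.05)

    out_beta = np.empty((iters, p))
    out_sigma = np.empty(iters)
    out_d = np.empty((iters, n_lat))
    out_sd = np.empty((iters, n_miss))
    prior_prec = eye / coef_scale**2
    mh_step = 0.35
    mh_accept = 0

    for it in range(warmup + iters):
        # coefficients | latents, sigma: conjugate normal
        A = Xw.T @ Xw / sigma**2 + prior_prec
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Xw.T @ y / sigma**2)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)

        # sigma | rest: slice sample on log sigma, half-normal prior
        resid = y - Xw @ beta
        ssr = float(resid @ resid)

        def log_post(lam, _ssr=ssr):
            return (-(n - 1) * lam - 0.5 * _ssr * math.exp(-2 * lam)
                    - math.exp(2 * lam) / (2 * sigma_scale**2))

        sigma = math.exp(_slice_sample_log(math.log(sigma), log_post, rng))

        if n_lat:
            # latent densities | beta, sigma: truncated-normal conjugate update
            b = beta[dens_col] + beta[inter_col] * forest[lat]
            Xw[lat, dens_col] = 0.0
            Xw[lat, inter_col] = 0.0
            rest = Xw[lat] @ beta
            prec = b**2 / sigma**2 + 1.0 / s**2
            mu = (b * (y[lat] - rest) / sigma**2 + d_obs / s**2) / prec
            d = _truncated_normal(rng, mu, 1.0 / np.sqrt(prec))
            Xw[lat, dens_col] = d
            Xw[lat, inter_col] = d * forest[lat]

        if n_miss:
            # imputed population sds | latent densities: log-scale RW Metropolis
            eta = np.log(sd_pop)
            eta_new = eta + mh_step * rng.standard_normal(n_miss)
            gap2 = (d_obs[miss] - d[miss])**2 * area_miss**2
            line = imput.intercept + imput.slope * pop_mean_miss

            def log_target(e):
                sd_ = np.exp(e)
                return -0.5 * gap2 * np.exp(-2 * e) - (sd_ - line)**2 / (2 * tau**2)

            accept = np.log(rng.uniform(size=n_miss)) < log_target(eta_new) - log_target(eta)
            sd_pop = np.where(accept, np.exp(eta_new), sd_pop)
            s[miss] = sd_pop / area_miss
            if it < warmup:
                # tune the proposal toward ~40% acceptance during warmup
                mh_accept += int(accept.sum())
                if (it + 1) % 50 == 0:
                    rate = mh_accept / (50 * n_miss)
                    mh_step = float(np.clip(mh_step * math.exp(rate - 0.4), 0.05, 2.0))
                    mh_accept = 0

        if it >= warmup:
            j = it - warmup
            out_beta[j] = beta
            out_sigma[j] = sigma
            if n_lat:
                out_d[j] = d
            if n_miss:
                out_sd[j] = sd_pop
    return out_beta, out_sigma, out_d, out_sd


def _standardize(X: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale the continuous non-latent columns; return (Xw, center, scale)."""
    center = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    for k, name in enumerate(names):
        if name in _STANDARDIZED:
            col = X[:, k]
            sd = col.std(ddof=0)
            if sd > 0:
                center[k] = col.mean()
                scale[k] = sd
    Xw = (X - center) / scale
    return Xw, center, scale


def _destandardize_beta(beta_w: np.ndarray, center: np.ndarray,
                        scale: np.ndarray) -> np.ndarray:
    """Map working-scale coefficient draws back to the analysis scale."""
    beta = beta_w / scale
    beta[..., 0] = beta_w[..., 0] - np.sum(
        beta_w[..., 1:] * (center[1:] / scale[1:]), axis=-1)
    return beta


def _estimate_tau(records: Sequence[PARecord], imput: ImputationConfig) -> float:
    """Residual scale of the mean-sd line from records reporting an sd."""
    if imput.residual_sd is not None:
        return imput.residual_sd
    resid = [rec.elephant_pop_sd - (imput.intercept + imput.slope * rec.elephant_pop_mean)
             for rec in records
             if rec.uncertainty_form == "sd" and rec.elephant_pop_mean is not None]
    if len(resid) < 3:
        return 100.0
    return max(float(np.std(resid, ddof=1)), 10.0)


def fit_visitation_model(records: Sequence[PARecord],
                         config: Optional[PipelineConfig] = None) -> PosteriorFit:
    """Fit the errors-in-variables visitation model to records with visits.

    Same seed and configuration reproduce the draw matrices exactly.
    """
    config = config or PipelineConfig()
    fit_records = [r for r in records if r.visits is not None]
    if len(fit_records) < 20:
        raise FitError(f"need >= 20 records with visits, got {len(fit_records)}")
    design = build_design(fit_records)
    tau = _estimate_tau(fit_records, config.imputation)

    Xw, center, scale = _standardize(design.X, design.names)
    lat = design.latent_idx
    miss_mask = np.isnan(design.s_obs)
    miss = np.flatnonzero(miss_mask)
    s_known = design.s_obs.copy()
    s_known[miss_mask] = 1.0  # placeholder, overwritten from imputed sds

    mcmc = config.mcmc
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    betas, sigmas, ds, sds = [], [], [], []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        b, sg, dd, sd = _run_chain(
            rng, design.y, Xw.copy(), _DENSITY, _INTERACTION, design.forest,
            lat, design.d_obs, s_known, miss, design.pop_mean[miss],
            design.censused_area[miss], tau, config.imputation,
            config.priors.coef_scale, config.priors.sigma_scale,
            mcmc.warmup_iters, mcmc.sampling_iters)
        betas.append(b)
        sigmas.append(sg)
        ds.append(dd)
        sds.append(sd)

    beta_w = np.stack(betas)
    beta = _destandardize_beta(beta_w, center, scale)
    lat_ids = [design.pa_ids[i] for i in lat]
    miss_ids = [design.pa_ids[lat[j]] for j in miss]
    return PosteriorFit(
        names=design.names,
        beta=beta,
        sigma=np.stack(sigmas),
        latent_density=np.stack(ds),
        imputed_sd=np.stack(sds),
        latent_pa_ids=lat_ids,
        imputed_pa_ids=miss_ids,
        covariate_means=design.X.mean(axis=0),
        seed=mcmc.seed,
    )


# ---------------------------------------------------------------------------
# prediction and fit evaluation
# ---------------------------------------------------------------------------

@dataclass
class VisitPrediction:
    draws: np.ndarray
    median: float


def predict_visits(fit: PosteriorFit, density: float,
                   covariates: str | dict = "at_means",
                   forest: Optional[bool] = None) -> VisitPrediction:
    """Posterior-predictive annual visits at a given elephant density.

    Non-density covariates are held at their fit-data means ("at_means") or
    set explicitly via a {predictor: design-scale value} mapping. ``forest``
    overrides both the forest main effect and the density x forest
    interaction; when None the forest column stays at its mean and the
    interaction uses that mean.
    """
    if density < 0:
        raise ValueError("density must be nonnegative")
    x = fit.covariate_means.copy()
    if isinstance(covariates, dict):
        for name, value in covariates.items():
            x[fit.names.index(name)] = value
    elif covariates != "at_means":
        raise ValueError(f"unknown covariates mode {covariates!r}")
    dens_idx = fit.names.index("elephant_density")
    inter_idx = fit.names.index("density_forest") if "density_forest" in fit.names else None
    forest_idx = fit.names.index("forest") if "forest" in fit.names else None
    forest_val = x[forest_idx] if forest_idx is not None else 0.0
    if forest is not None:
        forest_val = float(forest)
        if forest_idx is not None:
            x[forest_idx] = forest_val
    x[dens_idx] = density
    if inter_idx is not None:
        x[inter_idx] = density * forest_val
    lp = fit.beta_flat() @ x
    draws = np.exp(lp)
    return VisitPrediction(draws=draws, median=float(np.median(draws)))


def model_fit_r2(fit: PosteriorFit, records: Sequence[PARecord],
                 max_draws: int = 2000) -> tuple[float, float, float]:
    """OLS of observed log visits on median posterior-predicted log visits.

    Returns (slope, intercept, r_squared); the regression mirrors a
    predicted-vs-actual evaluation of the fitted model.
    """
    fit_records = [r for r in records if r.visits is not None]
    if len(fit_records) < 3:
        raise ValueError("need at least 3 records with observed visits")
    design = build_design(fit_records)
    beta = fit.beta_flat()
    d_lat = fit.latent_density.reshape(-1, fit.latent_density.shape[-1])
    if len(beta) > max_draws:
        idx = np.linspace(0, len(beta) - 1, max_draws).astype(int)
        beta = beta[idx]
        d_lat = d_lat[idx]
    lat_pos = {pa: j for j, pa in enumerate(fit.latent_pa_ids)}

    Xnd = design.X.copy()
    dens_plug = Xnd[:, _DENSITY].copy()
    Xnd[:, _DENSITY] = 0.0
    Xnd[:, _INTERACTION] = 0.0
    base = beta @ Xnd.T                       # (draws, n)
    b = beta[:, _DENSITY][:, None] + beta[:, _INTERACTION][:, None] * design.forest[None, :]
    dens = np.tile(dens_plug, (len(beta), 1))
    for i, pa in enumerate(design.pa_ids):
        j = lat_pos.get(pa)
        if j is not None:
            dens[:, i] = d_lat[:, j]
    pred = np.median(base + b * dens, axis=0)
    res = stats.linregress(pred, design.y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# within-site (single-PA time series) model
# ---------------------------------------------------------------------------

WITHIN_SITE_FULL = ("intercept", "log_area", "log_gdp", "elephant_density")
WITHIN_SITE_REDUCED = ("intercept", "elephant_density")


def fit_within_site(panel: pd.DataFrame,
                    predictors: Sequence[str] = ("area", "gdp", "density"),
                    config: Optional[PipelineConfig] = None) -> PosteriorFit:
    """Bayesian log-linear regression of visits on a single PA's time series.

    Densities are observed here (no measurement-error component). ``panel``
    needs columns year, visits, area_km2, country_gdp, elephant_density;
    ``predictors`` is a subset of {"area", "gdp", "density"}.
    """
    config = config or PipelineConfig()
    if len(panel) < 10:
        raise FitError("need at least 10 time points")
    if (panel["visits"] <= 0).any():
        raise TransformError("visits must be positive to log-transform")
    y = np.log(panel["visits"].to_numpy(dtype=float))
    cols = [("intercept", np.ones(len(panel)))]
    if "area" in predictors:
        cols.append(("log_area", np.log(panel["area_km2"].to_numpy(dtype=float))))
    if "gdp" in predictors:
        cols.append(("log_gdp", np.log(panel["country_gdp"].to_numpy(dtype=float))))
    if "density" in predictors:
        cols.append(("elephant_density", panel["elephant_density"].to_numpy(dtype=float)))
    names = tuple(n for n, _ in cols)
    X = np.column_stack([c for _, c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design columns are collinear to machine precision")

    center = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    for k, name in enumerate(names):
        if name.startswith("log_"):
            sd = X[:, k].std(ddof=0)
            if sd > 0:
                center[k] = X[:, k].mean()
                scale[k] = sd
    Xw = (X - center) / scale

    mcmc = config.mcmc
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    empty = np.empty(0)
    betas, sigmas = [], []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        b, sg, _, _ = _run_chain(
            rng, y, Xw.copy(), 0, 0, np.zeros(len(y)),
            np.empty(0, dtype=int), empty, empty, np.empty(0, dtype=int),
            empty, empty, 1.0, config.imputation,
            config.priors.coef_scale, config.priors.sigma_scale,
            mcmc.warmup_iters, mcmc.sampling_iters)
        betas.append(b)
        sigmas.append(sg)
    beta = _destandardize_beta(np.stack(betas), center, scale)
    zero = np.zeros((mcmc.chains, mcmc.sampling_iters, 0))
    return PosteriorFit(
        names=names, beta=beta, sigma=np.stack(sigmas),
        latent_density=zero, imputed_sd=zero,
        latent_pa_ids=[], imputed_pa_ids=[],
        covariate_means=X.mean(axis=0), seed=mcmc.seed,
    )
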