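"""Synthetic protected-area tables with the statistical structure the
visitation analysis assumes.

The generator emulates the study design: 216 PAs with elephants plus 54
elephant-free PAs with visitor data (164 PAs with visits in total, 110 of
them holding elephants); 43% of elephant populations report an sd, 12% a
range read as a 95% interval, and the rest no uncertainty; roughly 58 of the
216 elephant populations exceed 1,000 animals. Log visits are generated from
the same log-linear model the fit assumes, using the *latent true* density,
and the census mean is a noisy observation of the true population with the
record's sd. A companion truth table carries the latent values for test
harnesses; the PA table itself has exactly the real-data schema.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import Z_975
from .io import REGIONS, PARecord, SpendEstimateSet

#: Default true coefficients on the analysis (design) scale.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": 7.3,
    "log_area": -0.3,
    "elephant_density": 1.55,
    "forest": -1.0,
    "density_forest": -2.0,
    "lion": 1.0,
    "attractiveness": 0.1,
    "log_nearby_pop": -0.3,
    "log_accessibility": -0.5,
    "log_country_ppp": 0.8,
}


class CovariateRanges(BaseModel):
    """Marginal distributions of the fixed covariates (log-uniform ranges,
    Bernoulli probabilities, integer score range)."""

    area_km2: tuple[float, float] = (10.0, 1e4)
    nearby_population: tuple[float, float] = (1e3, 1e7)
    accessibility_minutes: tuple[float, float] = (30.0, 3000.0)
    country_ppp: tuple[float, float] = (1e3, 3e4)
    p_forest: float = 0.25
    p_lion: float = 0.6
    #: density (km^-2) for large (>1,000) populations; censused area = pop/density
    density_large: tuple[float, float] = (0.3, 2.0)
    pop_small: tuple[float, float] = (10.0, 900.0)
    pop_large: tuple[float, float] = (1100.0, 3e4)
    #: censused area (km^2) for small populations; density = pop/area, so small
    #: herds sit at low density over large census zones, as in real surveys
    area_small: tuple[float, float] = (500.0, 1e4)


class SyntheticParams(BaseModel):
    """Knobs of the synthetic study; defaults reproduce the study design."""

    n_pas: int = Field(default=216, gt=0)            # PAs with elephants
    n_no_elephant: int = Field(default=54, ge=0)     # visit-only PAs, no elephants
    n_with_visits: int = Field(default=164, gt=0)    # total PAs with visits
    true_coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    residual_sd: float = Field(default=1.2, ge=0)
    frac_sd_form: float = 0.43
    frac_range_form: float = 0.12
    frac_large_pop: float = 58 / 216
    sd_line_intercept: float = 192.0
    sd_line_slope: float = 0.122
    sd_line_jitter: float = 60.0
    obs_noise_scale: float = 1.0   # 0 => census mean equals the true population
    pike_range: tuple[float, float] = (0.0, 0.12)
    covariates: CovariateRanges = CovariateRanges()
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticParams":
        if self.frac_sd_form + self.frac_range_form > 1:
            raise ValueError("frac_sd_form + frac_range_form must be <= 1")
        if not (self.n_no_elephant <= self.n_with_visits <= self.n_pas + self.n_no_elephant):
            raise ValueError(
                "n_with_visits must lie between n_no_elephant and n_pas + n_no_elephant")
        return self


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), n))


def generate_pa_table(params: Optional[SyntheticParams] = None,
                      ) -> tuple[list[PARecord], pd.DataFrame]:
    """Generate PA records and their latent-truth companion table.

    Returns ``(records, truth)`` where ``truth`` has one row per record with
    the latent density, true population, the sd used for census noise, and
    the noiseless linear predictor of log visits.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed)
    cov = params.covariates
    beta = params.true_coefficients
    n_eleph = params.n_pas
    n_total = n_eleph + params.n_no_elephant

    region = rng.choice(REGIONS, size=n_total, p=[0.25, 0.3, 0.3, 0.15])
    iucn = rng.choice(["II", "III", "IV", "V", "VI"], size=n_total,
                      p=[0.5, 0.1, 0.2, 0.1, 0.1])
    area = _log_uniform(rng, *cov.area_km2, n_total)
    forest = rng.uniform(size=n_total) < cov.p_forest
    lion = rng.uniform(size=n_total) < cov.p_lion
    attract = rng.integers(1, 6, size=n_total)
    nearby = _log_uniform(rng, *cov.nearby_population, n_total)
    access = _log_uniform(rng, *cov.accessibility_minutes, n_total)
    ppp = _log_uniform(rng, *cov.country_ppp, n_total)
    pike = rng.uniform(*params.pike_range, size=n_total)
    pike[n_eleph:] = 0.0  # no elephants, no poaching-driven decline

    # --- latent elephant populations (first n_eleph records) ---
    n_large = round(params.frac_large_pop * n_eleph)
    true_pop = np.zeros(n_total)
    true_density = np.zeros(n_total)
    censused = np.full(n_total, np.nan)
    large = np.zeros(n_total, dtype=bool)
    large[rng.choice(n_eleph, size=n_large, replace=False)] = True
    for i in range(n_eleph):
        if large[i]:
            true_pop[i] = _log_uniform(rng, *cov.pop_large, 1)[0]
            true_density[i] = rng.uniform(*cov.density_large)
            censused[i] = true_pop[i] / true_density[i]
        else:
            true_pop[i] = _log_uniform(rng, *cov.pop_small, 1)[0]
            censused[i] = _log_uniform(rng, *cov.area_small, 1)[0]
            true_density[i] = true_pop[i] / censused[i]

    # uncertainty-form assignment: sd / range / none, deterministic counts
    n_sd = round(params.frac_sd_form * n_eleph)
    n_range = round(params.frac_range_form * n_eleph)
    forms = np.array(["none"] * n_total, dtype=object)
    order = rng.permutation(n_eleph)
    forms[order[:n_sd]] = "sd"
    forms[order[n_sd:n_sd + n_range]] = "range"

    # census observation: mean = truth + noise with the record's sd
    sd_true = np.zeros(n_total)
    pop_mean = np.full(n_total, np.nan)
    pop_sd = np.full(n_total, np.nan)
    pop_lo = np.full(n_total, np.nan)
    pop_hi = np.full(n_total, np.nan)
    for i in range(n_eleph):
        line = params.sd_line_intercept + params.sd_line_slope * true_pop[i]
        sd_true[i] = max(line + params.sd_line_jitter * rng.standard_normal(),
                         1.0) * params.obs_noise_scale
        pop_mean[i] = max(true_pop[i] + sd_true[i] * rng.standard_normal(), 1.0)
        if forms[i] == "sd":
            pop_sd[i] = sd_true[i]
        elif forms[i] == "range":
            half = Z_975 * sd_true[i]
            pop_lo[i] = max(pop_mean[i] - half, 0.0)
            pop_hi[i] = pop_mean[i] + half

    # --- visits for the n_with_visits subset ---
    n_eleph_visits = params.n_with_visits - params.n_no_elephant
    has_visits = np.zeros(n_total, dtype=bool)
    has_visits[rng.choice(n_eleph, size=n_eleph_visits, replace=False)] = True
    has_visits[n_eleph:] = True

    lp = (beta["intercept"]
          + beta["log_area"] * np.log(area)
          + beta["elephant_density"] * true_density
          + beta["forest"] * forest
          + beta["density_forest"] * true_density * forest
          + beta["lion"] * lion
          + beta["attractiveness"] * attract
          + beta["log_nearby_pop"] * np.log(nearby)
          + beta["log_accessibility"] * np.log(access)
          + beta["log_country_ppp"] * np.log(ppp))
    visits = np.exp(lp + params.residual_sd * rng.standard_normal(n_total))

    records = []
    for i in range(n_total):
        records.append(PARecord(
            pa_id=f"PA{i:03d}",
            name=f"Synthetic PA {i}",
            country=f"C{region[i][:1].upper()}",
            region=str(region[i]),
            iucn_category=str(iucn[i]),
            area_km2=float(area[i]),
            visits=float(visits[i]) if has_visits[i] else None,
            elephant_pop_mean=float(pop_mean[i]) if i < n_eleph else None,
            elephant_pop_sd=float(pop_sd[i]) if forms[i] == "sd" else None,
            elephant_pop_lo=float(pop_lo[i]) if forms[i] == "range" else None,
            elephant_pop_hi=float(pop_hi[i]) if forms[i] == "range" else None,
            censused_area_km2=float(censused[i]) if i < n_eleph else None,
            forest=bool(forest[i]),
            lion=bool(lion[i]),
            natural_attractiveness=int(attract[i]),
            nearby_population=float(nearby[i]),
            accessibility_minutes=float(access[i]),
            country_ppp=float(ppp[i]),
            poach_decline_rate=float(pike[i]),
        ))
    truth = pd.DataFrame({
        "pa_id": [r.pa_id for r in records],
        "true_population": true_pop,
        "true_density": true_density,
        "true_sd": sd_true,
        "linear_predictor": lp,
        "has_visits": has_visits,
        "uncertainty_form": forms,
    })
    return records, truth


def generate_spend_estimates(n_direct: int = 36, n_mult: int = 24,
                             direct_mean: float = 200.0, mult_mean: float = 2.5,
                             mult_sd: float = 0.8, seed: int = 0) -> SpendEstimateSet:
    """Literature-style spend estimates: exponential direct spend (USD per
    visit) and Gaussian multipliers truncated at 1."""
    if n_direct <= 0 or n_mult <= 0:
        raise ValueError("estimate counts must be positive")
    if direct_mean <= 0:
        raise ValueError("direct_mean must be positive")
    rng = np.random.default_rng(seed)
    direct = rng.exponential(direct_mean, size=n_direct)
    direct = np.maximum(direct, 1e-9)
    if mult_sd == 0:
        mult = np.full(n_mult, max(mult_mean, 1.0))
    else:
        from scipy import stats
        a = (1.0 - mult_mean) / mult_sd
        mult = stats.truncnorm.rvs(a, np.inf, loc=mult_mean, scale=mult_sd,
                                   size=n_mult, random_state=rng)
    return SpendEstimateSet(direct_spend_usd=direct.tolist(),
                            multipliers=mult.tolist())


#: Default true coefficients of the reduced within-site model.
DEFAULT_WITHIN_SITE_COEFFICIENTS: dict[str, float] = {
    "intercept": 2.0,
    "log_area": 0.47,
    "log_gdp": 0.3,
    "elephant_density": 0.67,
}


def generate_within_site_panel(n_years: int = 56,
                               true_coefficients: Optional[dict[str, float]] = None,
                               residual_sd: float = 0.35,
                               seed: int = 0) -> pd.DataFrame:
    """Single-site annual panel: growing park area and national GDP, a rising
    elephant density, and log visits from the reduced log-linear model."""
    if n_years < 10:
        raise ValueError("n_years must be >= 10")
    beta = dict(DEFAULT_WITHIN_SITE_COEFFICIENTS)
    if true_coefficients:
        beta.update(true_coefficients)
    rng = np.random.default_rng(seed)
    years = np.arange(1954, 1954 + n_years)
    t = np.arange(n_years)
    area = 100.0 * np.exp(0.03 * t) * np.exp(0.02 * rng.standard_normal(n_years))
    gdp = 2e10 * np.exp(0.025 * t) * np.exp(0.01 * rng.standard_normal(n_years))
    # density trends upward but with enough year-to-year variation to be
    # separable from the smooth area/GDP growth trends
    density = np.clip(0.2 + 2.0 * t / n_years + 0.35 * rng.standard_normal(n_years),
                      0.01, None)
    lp = (beta["intercept"] + beta["log_area"] * np.log(area)
          + beta["log_gdp"] * np.log(gdp) + beta["elephant_density"] * density)
    visits = np.exp(lp + residual_sd * rng.standard_normal(n_years))
    return pd.DataFrame({
        "year": years, "visits": visits, "area_km2": area,
        "country_gdp": gdp, "elephant_density": density,
    })
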