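"""Pipeline configuration: MCMC settings, priors, valuation and cost constants."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

#: 97.5% standard-normal quantile used to convert population ranges to sds.
Z_975 = 1.959964

#: Anti-poaching spending (USD km^-2) at which large elephant populations are
#: stable: $215 in 1981 dollars, $565 after CPI inflation to 2016.
BENCHMARK_1981_USD_KM2 = 215.0
BENCHMARK_2016_USD_KM2 = 565.0
DEFAULT_INFLATION_FACTOR = BENCHMARK_2016_USD_KM2 / BENCHMARK_1981_USD_KM2


class MCMCConfig(BaseModel):
    chains: int = 4
    warmup_iters: int = 1000
    sampling_iters: int = 1000
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "MCMCConfig":
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (R-hat needs multiple chains)")
        if self.warmup_iters <= 0 or self.sampling_iters <= 0:
            raise ValueError("iteration counts must be positive")
        return self


class PriorConfig(BaseModel):
    """Vague priors: Normal(0, coef_scale^2) on standardized-scale coefficients,
    half-Normal(0, sigma_scale) on the residual scale."""

    coef_scale: float = 10.0
    sigma_scale: float = 5.0


class ValuationConfig(BaseModel):
    n_draws: int = Field(default=100_000, gt=0)
    seed: int = 0


class CostConfig(BaseModel):
    benchmark_1981_usd: float = BENCHMARK_1981_USD_KM2
    inflation_factor: float = DEFAULT_INFLATION_FACTOR
    slope_b: float = Field(default=0.05, gt=0)
    large_pop_threshold: float = 1000.0


class TransformConfig(BaseModel):
    """Which covariates enter the design on the natural-log scale."""

    logged: tuple[str, ...] = (
        "area_km2", "nearby_population", "accessibility_minutes", "country_ppp",
    )


class ConvergenceConfig(BaseModel):
    rhat_max: float = 1.01
    ess_min: float = 400.0


class ImputationConfig(BaseModel):
    """Linear mean-sd relation for elephant population estimates.

    The line sd = intercept + slope * mean is used both to impute missing
    population sds inside the model and as the generator's mean-sd relation.
    residual_sd, when None, is estimated from the records that report an sd.
    """

    intercept: float = 192.0
    slope: float = Field(default=0.122, ge=0)
    residual_sd: Optional[float] = None


class PipelineConfig(BaseModel):
    mcmc: MCMCConfig = MCMCConfig()
    priors: PriorConfig = PriorConfig()
    valuation: ValuationConfig = ValuationConfig()
    cost: CostConfig = CostConfig()
    transforms: TransformConfig = TransformConfig()
    convergence: ConvergenceConfig = ConvergenceConfig()
    imputation: ImputationConfig = ImputationConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def test_scale_config(seed: int = 0, **overrides) -> PipelineConfig:
    """A desk-scale configuration: short chains, 20k valuation draws."""
    cfg = PipelineConfig(
        mcmc=MCMCConfig(chains=2, warmup_iters=400, sampling_iters=400, seed=seed),
        valuation=ValuationConfig(n_draws=20_000, seed=seed),
    )
    return cfg.model_copy(update=overrides)


def paper_scale_config(seed: int = 0) -> PipelineConfig:
    """The study-scale configuration: 4 chains x 25k warmup + 25k sampling,
    100,000 valuation draws."""
    return PipelineConfig(
        mcmc=MCMCConfig(chains=4, warmup_iters=25_000, sampling_iters=25_000, seed=seed),
        valuation=ValuationConfig(n_draws=100_000, seed=seed),
    )
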