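import numpy as np
import pytest

from elevisits.config import MCMCConfig, PipelineConfig, ValuationConfig
from elevisits.synth import SyntheticParams, generate_pa_table, generate_spend_estimates


def fast_config(seed: int = 0, chains: int = 2, warmup: int = 300,
                sampling: int = 300, n_draws: int = 5000) -> PipelineConfig:
    return PipelineConfig(
        mcmc=MCMCConfig(chains=chains, warmup_iters=warmup,
                        sampling_iters=sampling, seed=seed),
        valuation=ValuationConfig(n_draws=n_draws, seed=seed),
    )


@pytest.fixture(scope="session")
def synthetic_study():
    """Default-condition synthetic study: records plus latent-truth table."""
    return generate_pa_table(SyntheticParams(seed=42))


@pytest.fixture(scope="session")
def spend_estimates():
    return generate_spend_estimates(seed=42)


@pytest.fixture(scope="session")
def fitted(synthetic_study):
    """A single shared fit of the visitation model at desk scale."""
    from elevisits.model import fit_visitation_model
    records, _ = synthetic_study
    return fit_visitation_model(records, fast_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
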