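import warnings

import numpy as np
import pytest

from mbttest import PriorSettings, SamplerSettings, TwoSampleData, summarize

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def toy_data() -> TwoSampleData:
    """4+4 observations, small enough for the tensor-grid oracle."""
    return TwoSampleData([-1.1, -0.2, 0.3, 0.9], [0.1, 0.8, 1.4, 2.0])


@pytest.fixture(scope="session")
def toy_stats(toy_data):
    return summarize(toy_data)


@pytest.fixture(scope="session")
def priors() -> PriorSettings:
    return PriorSettings()


@pytest.fixture(scope="session")
def sampler_settings() -> SamplerSettings:
    """Full-quality settings for single fits (strict R-hat gate)."""
    return SamplerSettings(seed=0)


@pytest.fixture(scope="session")
def sweep_settings() -> SamplerSettings:
    """Reduced settings for many-dataset sweeps (relaxed R-hat gate)."""
    return SamplerSettings(
        n_walkers=16, n_warmup=250, n_keep=250, n_bridge=1500,
        max_posterior_draws=2000, rhat_max=1.05, seed=0,
    )


@pytest.fixture(scope="session")
def replication_stats():
    """Summary statistics of the hypothetical 20+20 replication sample."""
    from mbttest import SummaryStats

    return SummaryStats(n1=20, mean1=12.35, sd1=12.18, n2=20, mean2=3.65, sd2=3.94)
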