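import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermopanel.model import AnalysisConfig
from thermopanel.synthetic import SyntheticConfig, panel_strains

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def synth_config():
    return SyntheticConfig(seed=11)


@pytest.fixture
def zero_noise_config():
    return SyntheticConfig(noise_sd=0.0, seed=11)


@pytest.fixture
def analysis_config(synth_config):
    return AnalysisConfig(
        loci=synth_config.loci,
        path_order=synth_config.locus_names,
        n_boot=500,
        rng_seed=11,
    )


@pytest.fixture
def growth_table(synth_config):
    strains = panel_strains(synth_config)
    from thermopanel.synthetic import generate_growth_panel

    return generate_growth_panel(synth_config, strains, 39.0)
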