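import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gcpanel import GeneratorConfig, generate_cohort, load_reference_panel

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """Pooled-size synthetic cohort (31 sensitive / 16 resistant), fixed seed."""
    config = GeneratorConfig(seed=20240915)
    return generate_cohort(config, panel=panel)


@pytest.fixture(scope="session")
def big_cohort(panel):
    """Large cohort for rate-calibration checks (5000 per group)."""
    config = GeneratorConfig(
        n_sensitive=5000, n_resistant=5000, loading=0.0, seed=7
    )
    return generate_cohort(config, panel=panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
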