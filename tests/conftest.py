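import numpy as np
import pytest

import larvalfit as lf
from larvalfit.gompertz import FitConfig, ModelSpec

TRUE_SPEC = ModelSpec("Location + Salinity + Density",
                      "Location + Salinity * Density")


@pytest.fixture(scope="session")
def design():
    return lf.build_design()


@pytest.fixture(scope="session")
def default_dataset(design):
    return lf.simulate_dataset(design, lf.default_config(seed=42))


@pytest.fixture(scope="session")
def strong_dataset(design):
    return lf.simulate_dataset(design, lf.strong_effects_config(seed=7))


@pytest.fixture(scope="session")
def strong_model_table(strong_dataset):
    """One full 17-model AICc table on strong-effect data (shared: ~2 s)."""
    return lf.build_model_table(strong_dataset.growth,
                                strong_dataset.units_frame,
                                FitConfig(n_restarts=3, seed=11))


def rep_seeds(root: int, n: int) -> list[int]:
    rng = np.random.default_rng(root)
    return [int(s) for s in rng.integers(0, 2 ** 31, size=n)]
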