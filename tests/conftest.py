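import numpy as np
import pandas as pd
import pytest

from soilsom import MetalPanel, make_scene
from soilsom.risk import METALS


@pytest.fixture(scope="session")
def unit_panel() -> MetalPanel:
    """Panel with all reference concentrations 1 mg/kg (CF = concentration)."""
    return MetalPanel(reference={m: 1.0 for m in METALS})


@pytest.fixture(scope="session")
def small_scene():
    """A reduced synthetic scene shared across tests (36 towns, 200 samples)."""
    return make_scene(seed=7, n_towns=36, n_samples=200)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sample_frame() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    n = 12
    data = {"sample_id": [f"S{i}" for i in range(n)],
            "lon": rng.uniform(0, 1, n), "lat": rng.uniform(0, 1, n)}
    for m in METALS:
        data[m] = rng.lognormal(0.0, 0.4, n)
    return pd.DataFrame(data)
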