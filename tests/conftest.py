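import numpy as np
import pandas as pd
import pytest

from soilrisk.io import ExposureProfile, MetalParams, SampleTable
from soilrisk._defaults import METALS
from soilrisk.synth import default_spec, generate_cohort


@pytest.fixture(scope="session")
def params():
    return MetalParams.defaults()


@pytest.fixture(scope="session")
def profiles():
    return {c: ExposureProfile.defaults(c) for c in ("adult", "child")}


@pytest.fixture(scope="session")
def cohort():
    """Default calibrated synthetic cohort (n=273, fixed seed) plus truth."""
    return generate_cohort(default_spec(seed=1))


def make_samples(conc: dict[str, list[float]], *, ph: float = 7.7,
                 coords=None) -> SampleTable:
    """Build a small SampleTable from per-metal concentration lists."""
    n = len(next(iter(conc.values())))
    rng = np.random.default_rng(0)
    if coords is None:
        coords = rng.uniform(0, 100, size=(n, 2))
    df = pd.DataFrame({"sample_id": [f"T{i}" for i in range(n)],
                       "x": coords[:, 0], "y": coords[:, 1],
                       "pH": [ph] * n})
    for m in METALS:
        df[m] = conc.get(m, [1.0] * n)
    return SampleTable(df)


@pytest.fixture
def toy4():
    """Four hand-set samples covering all eight metals."""
    return make_samples({
        "Hg": [0.01, 0.02, 0.05, 0.30],
        "Cr": [20.0, 40.0, 60.0, 300.0],
        "Cu": [10.0, 30.0, 90.0, 150.0],
        "Pb": [15.0, 30.0, 60.0, 200.0],
        "Zn": [40.0, 70.0, 120.0, 400.0],
        "As": [5.0, 15.0, 30.0, 60.0],
        "Cd": [0.05, 0.20, 0.70, 3.00],
        "Ni": [10.0, 25.0, 50.0, 250.0],
    })
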