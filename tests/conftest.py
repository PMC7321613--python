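import numpy as np
import pandas as pd
import pytest

from lipotherm import generate_cohort
from lipotherm.lipophilicity import SoczewinskiModel
from lipotherm.thermodynamics import VantHoffModel


@pytest.fixture(scope="session")
def cohort():
    """Default 14-compound cohort, seed 1: (measurements, truth)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def lipo_results(cohort):
    measurements, truth = cohort
    iso = measurements[measurements["temperature"] == truth.t_ref]
    return SoczewinskiModel(iso).fit()


@pytest.fixture(scope="session")
def thermo_results(cohort):
    measurements, truth = cohort
    series = measurements[measurements["phi"] == truth.phi_ref]
    return VantHoffModel(series).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(compound_id, modifier, phi, temperature, k):
    """Broadcast scalars/arrays into a canonical measurement frame."""
    phi, temperature, k = np.broadcast_arrays(
        np.atleast_1d(np.asarray(phi, float)),
        np.atleast_1d(np.asarray(temperature, float)),
        np.atleast_1d(np.asarray(k, float)),
    )
    df = pd.DataFrame({"phi": phi, "temperature": temperature, "k": k})
    df.insert(0, "modifier", modifier)
    df.insert(0, "compound_id", compound_id)
    return df
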