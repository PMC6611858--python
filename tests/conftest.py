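import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import pfjsim as pj
from pfjsim.scenario import _load_csv

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")

logging.getLogger("pfjsim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mean_knee() -> pj.KneeParams:
    return pj.load_case("mean")


@pytest.fixture(scope="session")
def mean_geometry(mean_knee) -> pj.KneeGeometry:
    return pj.build_knee(mean_knee)


@pytest.fixture(scope="session")
def contact_model(mean_geometry) -> pj.ContactModel:
    model = pj.ContactModel(mean_geometry)
    model.baseline()
    return model


@pytest.fixture(scope="session")
def materials() -> pj.MaterialTable:
    return pj.MaterialTable()


@pytest.fixture(scope="session")
def technique_lengths() -> pd.DataFrame:
    return _load_csv("technique_lengths.csv")


@pytest.fixture(scope="session")
def clinical_lengths() -> pd.DataFrame:
    return _load_csv("clinical_lengths.csv")


@pytest.fixture(scope="session")
def reference_stresses() -> pd.DataFrame:
    return _load_csv("reference_stresses.csv")


@pytest.fixture(scope="session")
def clinical_stresses() -> pd.DataFrame:
    return _load_csv("clinical_stresses.csv")


@pytest.fixture(scope="session")
def reference_pressures() -> pd.DataFrame:
    return _load_csv("reference_pressures.csv")


@pytest.fixture(scope="session")
def technique_results(mean_knee):
    """Full five-angle simulations of the native knee and the three
    reconstructions on the mean knee, shared across tests."""
    out = {}
    for tech in ("native", "anatomic", "non_anatomic_physiometric",
                 "non_anatomic_non_physiometric"):
        spec = pj.ReconstructionSpec.from_technique(tech)
        out[tech] = pj.run_case(mean_knee, spec)
    return out
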