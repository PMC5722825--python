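import numpy as np
import pytest

from atdyn import (
    CAParams,
    DrugResponse,
    FitnessFunctionSpec,
    GrowthParams,
    TreatmentSchedule,
)


@pytest.fixture(scope="session")
def reference_growth():
    """Division rates and tumour size of the reference simulation setup."""
    return GrowthParams()  # lambda_W = lambda_R = log(2)/10, N0 = 1e9


@pytest.fixture(scope="session")
def reference_response():
    return DrugResponse()  # IC50_W = 1, IC50_R = 100


@pytest.fixture(scope="session")
def mtd_schedule():
    return TreatmentSchedule(regime="MTD", rho_MTD=1.0, theta=5.0)


@pytest.fixture(scope="session")
def at_schedule():
    return TreatmentSchedule(regime="AT", rho_MTD=1.0, theta=5.0)


@pytest.fixture(scope="session")
def sigmoid_quarter():
    """Sigmoidal fitness with a 4-fold penalty for rare resistant cells."""
    return FitnessFunctionSpec(kind="sigmoidal", f_min=0.25, k=20.0, c=0.5)


@pytest.fixture(scope="session")
def small_ca_params():
    """A small lattice for fast CA unit tests."""
    return CAParams(grid_size=60)
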