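import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import livertwin as lt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cnbio():
    return lt.load_chip_preset("cnbio")


@pytest.fixture(scope="session")
def probe_compound():
    """Neutral, moderately lipophilic reference compound."""
    return lt.CompoundRecord(name="probe", logp=2.0, mw=350.0, fu_media=0.5, ionisation=0, rbp=1.0)


@pytest.fixture(scope="session")
def probe_params(cnbio, probe_compound):
    pp = lt.compound_parameters(probe_compound, cnbio)
    return lt.build_rate_constants(pp, cnbio, probe_compound.fu_media, cl_c=0.05)


def random_twin_parameters(rng: np.random.Generator, cl_c=None) -> lt.TwinParameters:
    """Moderate random kinetic parameter sets for solver property tests."""
    return lt.TwinParameters(
        k1=float(10 ** rng.uniform(-3, 0)),
        k2=float(10 ** rng.uniform(-3, 0)),
        k3=float(10 ** rng.uniform(-3, 0)),
        k4=float(10 ** rng.uniform(-3, 0)),
        cl_c=float(10 ** rng.uniform(-3, 0)) if cl_c is None else cl_c,
        v_m=float(10 ** rng.uniform(-1.5, 0.5)),
        v_i=float(10 ** rng.uniform(-3, -1)),
        v_c=float(10 ** rng.uniform(-3, -1)),
    )
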