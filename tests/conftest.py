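import numpy as np
import pytest
from hypothesis import settings

import glucoreg as g

settings.register_profile("repro", derandomize=True, deadline=None, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def patient1():
    return g.preset_patient("patient1")


@pytest.fixture(scope="session")
def all_patients():
    return [g.preset_patient(p) for p in g.PATIENT_IDS]


@pytest.fixture(scope="session")
def model1(patient1):
    return g.linearize(patient1)


@pytest.fixture(scope="session")
def weights():
    return g.published_weights()


@pytest.fixture(scope="session")
def gains():
    return g.published_gains()


@pytest.fixture(scope="session")
def sliding():
    return g.published_sliding_config()


@pytest.fixture(scope="session")
def insulin_free_patient():
    """Patient-1 rates with the insulin compartment at rest (Ib = I0 = X0 = 0).

    With zero basal and zero initial insulin the X and I states stay
    identically zero, so the open-loop glucose trajectory follows the
    exact closed form Gss + (G0 - Gss) * exp(-p1 * t).
    """
    return g.PatientParams(
        p1=0.012, p2=0.020, p3=5.3e-6, n=0.3, Ib=0.0, Gss=80.0, V1=12.0,
        G0=200.0, X0=0.0, I0=0.0, name="insulin-free",
    )


_SCENARIOS = {
    "A": lambda: g.scenario_hyperglycemia(),
    "A300": lambda: g.scenario_hyperglycemia(duration=300.0),
    "B": lambda: g.scenario_meal(),
    "C": lambda: g.scenario_stress(),
    "fault": lambda: g.scenario_sensor_fault(),
}


@pytest.fixture(scope="session")
def sim():
    """Session-cached closed-loop runner keyed by (patient, controller, scenario, seed)."""
    cache: dict = {}

    def run(patient="patient1", controller="lq-asmc", scenario="A", seed=0):
        key = (patient, controller, scenario, seed)
        if key not in cache:
            cache[key] = g.run_closed_loop(
                g.preset_patient(patient), controller, _SCENARIOS[scenario](), seed=seed
            )
        return cache[key]

    return run
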