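import pytest

from aopkit import (
    DetectionConfig,
    LinearCompliance,
    RespiratorySystem,
    VentCircuit,
    load_scenario,
)
from aopkit.simulate import low_flow_settings, vacv_settings


@pytest.fixture(scope="session")
def cfg():
    return DetectionConfig()


@pytest.fixture(scope="session")
def bench_circuit():
    return VentCircuit(ccirc=2.0)


@pytest.fixture(scope="session")
def small_circuit():
    """Near-rigid circuit: the simulator's stiff limit for oracle checks."""
    return VentCircuit(ccirc=1e-3)


@pytest.fixture(scope="session")
def linear_system():
    """The bench model without closure: Rrs 10, Crs 40 mL/cmH2O."""
    return RespiratorySystem(rrs=10.0, compliance=LinearCompliance(40.0))


@pytest.fixture(scope="session")
def settings_peep5():
    return vacv_settings(peep=5.0)


@pytest.fixture(scope="session")
def lowflow_peep5():
    return low_flow_settings(peep=5.0)


@pytest.fixture(scope="session")
def scenarios():
    return {name: load_scenario(name) for name in ("aop10", "control1", "control2")}
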