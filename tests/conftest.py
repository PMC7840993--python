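import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoshift.simulate import SimSpec, simulate_melt_curve

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # the curve-factory fixtures are pure functions of their
        # arguments, so sharing them across generated inputs is safe
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def grid():
    """The assay's standard 25-95 degC / 0.2 degC temperature grid."""
    return SimSpec().temperatures()


@pytest.fixture
def clean_curve_factory():
    """Noiseless flat-baseline melt curves with a known Tm."""

    def make(tm: float, dh_vh: float = 400.0):
        spec = SimSpec(
            tm0=tm,
            dh_vh=dh_vh,
            native_baseline=(30.0, 0.0),
            unfolded_baseline=(150.0, 0.0),
            noise_sd=0.0,
            quench_onset=tm + 8.0,
        )
        return simulate_melt_curve(spec)

    return make


@pytest.fixture
def titration_concs():
    """The dsDNA titration design: seven duplex concentrations, 0.5-10 uM."""
    return np.array([0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0])
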