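import numpy as np
import pytest

from cyclenose import (
    ExposurePlan,
    GasResponseModel,
    TemperatureProgram,
    make_fixtures,
    run_analysis,
)
from cyclenose.preprocess import Cycle


@pytest.fixture(scope="session")
def program():
    return TemperatureProgram()


@pytest.fixture(scope="session")
def clean_model():
    """Deterministic model: no noise, no drift, instantaneous transients."""
    return GasResponseModel(noise_sd=0.0, drift_per_hour=0.0, tau_gas_s=0.0, tau_temp_s=0.0)


@pytest.fixture(scope="session")
def noisy_model():
    return GasResponseModel()


def make_cycle(values, gas="SA", conc=0.0, phase="baseline", idx=0, standardized=True):
    values = np.asarray(values, float)
    return Cycle(
        values=values, cycle_index=idx, raw_mean=float(values.mean()),
        gas=gas, conc_ppb=conc, phase=phase, standardized=standardized,
    )


@pytest.fixture(scope="session")
def random_cycle(program):
    rng = np.random.default_rng(7)
    return make_cycle(rng.normal(0, 100, program.cycle_length_samples))


def air_then_gas_plan(gas="CH2O", conc=1000.0, air_cycles=1, gas_cycles=1, cycle_s=110.0):
    return ExposurePlan.from_tuples(
        [("SA", 0.0, air_cycles * cycle_s), (gas, conc, gas_cycles * cycle_s)]
    )


@pytest.fixture(scope="session")
def demo_analysis():
    """Full analysis of the demo study (paper-shaped: 3 VOCs + SA, 7 levels,
    ~42 observations per gas).  Shared across tests; ~2.5 min to compute."""
    return run_analysis(make_fixtures("demo", seed=1))
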