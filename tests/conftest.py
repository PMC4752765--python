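import numpy as np
import pytest

import neoblast as nb


@pytest.fixture(scope="session")
def params():
    return nb.default_parameters()


@pytest.fixture(scope="session")
def full_ss(params):
    """Closed-form full-model steady state at the reference food level."""
    return nb.solve_full_steady_state(450.0, params)


@pytest.fixture(scope="session")
def full_calib(full_ss, params):
    return nb.make_calibration(full_ss, params)


@pytest.fixture(scope="session")
def homeostatic_state(full_ss):
    return nb.FullState(t=0, N=full_ss.N_bar, D=full_ss.D_bar.copy(), Q=0.0)


# ---- long runs shared across test modules (each is a deterministic,
# ---- minutes-scale protocol; session scope avoids recomputation) ----

@pytest.fixture(scope="session")
def growth_result(params):
    """Food-shift protocol: Y_e 450 -> 400 at t=7 -> 480 at t=14, 20 % start."""
    schedule = nb.FoodSchedule(((0.0, 450.0), (7.0, 400.0), (14.0, 480.0)))
    return nb.run_growth_experiment(params, schedule, start_fraction=0.2)


@pytest.fixture(scope="session")
def fission_result(params):
    return nb.run_fission_experiment(params)


@pytest.fixture(scope="session")
def excision_result(params):
    return nb.run_excision_experiment(params)


@pytest.fixture(scope="session")
def xray_result(params):
    return nb.run_xray_experiment(params)


@pytest.fixture(scope="session")
def simplified_growth_result(params):
    """Single-class analogue of the growth protocol (Fig-7-style schedule)."""
    schedule = nb.FoodSchedule(((0.0, 240.0), (7.0, 200.0), (15.0, 160.0)))
    return nb.run_growth_experiment(params, schedule, start_fraction=0.2,
                                    model="simplified")
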