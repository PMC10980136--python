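import numpy as np
import pytest
from hypothesis import settings as _hsettings

from antimir import load_default_parameters, preclinical_regimen, simulate

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")
from antimir.cohort import sample_cohort
from antimir.dosing import Regimen
from antimir.model import Trajectory, initial_state


@pytest.fixture(scope="session")
def mouse_params():
    return load_default_parameters("mouse")


@pytest.fixture(scope="session")
def human_params():
    return load_default_parameters("human")


@pytest.fixture(scope="session")
def mouse_control(mouse_params):
    return simulate(mouse_params, preclinical_regimen("control"), t_grid=0.5)


@pytest.fixture(scope="session")
def mouse_antimir(mouse_params):
    return simulate(mouse_params, preclinical_regimen("anti_mir155"), t_grid=0.5)


@pytest.fixture(scope="session")
def small_cohort(human_params):
    return sample_cohort(human_params, n=12, seed=42)


def make_volume_trajectory(params, times, volumes, treatment_start=0.0):
    """Hand-built trajectory carrying a prescribed tumor-volume series (all
    other states at their drug-free equilibria)."""
    times = np.asarray(times, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    states = np.tile(initial_state(params, volumes[0]), (len(times), 1))
    states[:, 15] = volumes
    reg = Regimen(events=[], treatment_start=treatment_start,
                  follow_up_end=float(times[-1]))
    return Trajectory(time=times, states=states, params=params, regimen=reg)


@pytest.fixture(scope="session")
def volume_traj_factory(human_params):
    def factory(times, volumes, treatment_start=0.0, params=None):
        return make_volume_trajectory(params or human_params, times, volumes,
                                      treatment_start)
    return factory
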