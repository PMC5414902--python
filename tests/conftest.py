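"""Shared fixtures: schedules, ground-truth input functions, synthetic sessions."""

import numpy as np
import pytest

from petkin.curves import SessionMeta
from petkin.input_function import BloodSampleSeries
from petkin.schedules import (default_arterial_times, default_fine_grid,
                              default_frame_schedule)
from petkin.simulate import SyntheticCohortSpec, generate_session, true_parent_aif


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def fine_grid():
    return default_fine_grid()


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticCohortSpec(seed=1)


@pytest.fixture(scope="session")
def noiseless_spec():
    return SyntheticCohortSpec(seed=1, noise_cov=0.0)


@pytest.fixture(scope="session")
def truth_aif(default_spec):
    """Ground-truth parent-plasma input of one synthetic session."""
    return true_parent_aif(default_spec, "rat01", "D0+35")


@pytest.fixture(scope="session")
def noiseless_session(noiseless_spec):
    return generate_session(noiseless_spec, "rat01", "D0+35")


@pytest.fixture(scope="session")
def blood_series(noiseless_session):
    sd = noiseless_session
    return BloodSampleSeries(
        subject="rat01", session="D0+35",
        time_min=sd.blood_time_min,
        blood_kBq_per_mL=sd.blood_kBq_per_mL,
        parent_fraction=sd.parent_fraction,
        plasma_kBq_per_mL=sd.plasma_kBq_per_mL,
    )


@pytest.fixture
def meta():
    return SessionMeta(subject="rat01", session="D0+35",
                       dose_MBq=37.0, weight_g=250.0)


@pytest.fixture(scope="session")
def arterial_times():
    return default_arterial_times()
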