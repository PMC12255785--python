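import datetime as dt

import numpy as np
import pytest

from betadrift.distributions import BinGrid, daily_distributions
from betadrift.io_core import Hemisphere, MinuteSeries
from betadrift.synthetic import generate_synthetic_patient
from betadrift import profiles


def make_series(values, start="2024-01-01T00:00:00", step_s=60,
                patient="P1", hemisphere=Hemisphere.CH1):
    """MinuteSeries from a plain list of power values."""
    t0 = np.datetime64(start, "s")
    ts = t0 + np.arange(len(values)) * np.timedelta64(step_s, "s")
    return MinuteSeries(patient, hemisphere, ts, np.asarray(values, float))


@pytest.fixture(scope="session")
def one_day_series():
    """One full calendar day: 1440 one-minute samples, deterministic values."""
    rng = np.random.default_rng(42)
    return make_series(rng.uniform(1.0, 9.0, 1440))


@pytest.fixture(scope="session")
def toy_grid():
    return BinGrid.from_window(0.0, 10.0, n_bins=10)


@pytest.fixture(scope="session")
def nonlinear_patient():
    """The frozen regime-switching study patient (see betadrift.profiles)."""
    return generate_synthetic_patient(profiles.NONLINEAR_PATIENT)


@pytest.fixture(scope="session")
def nonlinear_dists(nonlinear_patient):
    series, _, truth = nonlinear_patient
    grid = BinGrid.from_window(*truth.p_window, n_bins=profiles.DESK_N_BINS)
    return daily_distributions(series, grid), grid


@pytest.fixture(scope="session")
def constant_patient():
    return generate_synthetic_patient(profiles.CONSTANT_PATIENT)
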