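import datetime as dt

import numpy as np
import pytest

import survcast as sv


@pytest.fixture(scope="session")
def surface():
    return sv.default_surface()


@pytest.fixture(scope="session")
def scenario():
    return sv.default_scenario()


@pytest.fixture(scope="session")
def sim_grid(surface, scenario):
    """One registry-scale simulated grid (aggregate fast path), seed fixed."""
    return sv.simulate_grid(surface, scenario, seed=123)


@pytest.fixture(scope="session")
def sim_fit(sim_grid):
    return sv.fit_grid(sim_grid)


@pytest.fixture(scope="session")
def exact_default_grid(surface, scenario):
    """Noise-free grid whose counts are exact expectations of the truth."""
    return sv.exact_grid(surface, scenario)


@pytest.fixture(scope="session")
def drift_surface():
    """Pure-drift truth (zero curvature): lies exactly in the model span."""
    return sv.TrueSurface(
        a_s=np.array([0.2, 0.9, 1.4, 1.8, 2.2]), drift=0.05, cohort_ref=2013.0
    )


@pytest.fixture
def toy_records():
    """Four patients of cohort 2000: one dies in interval 1, one in interval 2."""
    mk = lambda diag, death=None: sv.PatientRecord(
        diagnosis_date=dt.date.fromisoformat(diag),
        death_date=dt.date.fromisoformat(death) if death else None,
    )
    return [
        mk("2000-08-15", "2001-02-10"),  # dies ~0.5y after diagnosis
        mk("2000-10-01", "2002-04-20"),  # dies ~1.5y after diagnosis
        mk("2001-03-01"),
        mk("2001-06-30"),
    ]
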