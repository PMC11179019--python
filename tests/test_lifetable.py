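"""Grid construction: cohort assignment, counts, geometry, aggregation."""

import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survcast as sv
from survcast.errors import GridError, InputError


@pytest.mark.parametrize(
    "date, cohort",
    [
        ("1997-07-01", 1997),
        ("1998-06-30", 1997),
        ("1998-07-01", 1998),
        ("2017-12-31", 2017),
        ("2018-06-30", 2017),
    ],
)
def test_mid_year_cohort_assignment(date, cohort):
    assert sv.assign_cohort_year(dt.date.fromisoformat(date)) == cohort


def test_cohort_outside_study_window_rejected():
    with pytest.raises(InputError, match="outside the study window"):
        sv.assign_cohort_year(dt.date(1990, 1, 1), cohort_range=(1997, 2017))


def test_no_deaths_gives_unit_rates():
    records = [
        sv.PatientRecord(diagnosis_date=dt.date(2000, 9, 1)) for _ in range(10)
    ]
    grid = sv.build_interval_grid(records, dt.date(2010, 1, 1))
    obs = grid.observed
    assert (obs["rate"] == 1.0).all() and len(obs) == 5


def test_toy_four_patient_interval_rates(toy_records):
    """Hand enumeration: one death before the first anniversary (r1 = 3/4),
    one between the first and second (r2 = 2/3)."""
    grid = sv.build_interval_grid(toy_records, dt.date(2010, 1, 1))
    assert grid.rate(1, 2000) == pytest.approx(3 / 4)
    assert grid.rate(2, 2000) == pytest.approx(2 / 3)
    assert grid.rate(3, 2000) == pytest.approx(1.0)


def test_registry_range_geometry(sim_grid):
    """Cohorts 1997-2017 followed to 2018-12-31: 95 observed cells, 70 in
    periods <= 2013 and 25 in 2014-2018."""
    obs = sim_grid.observed
    assert len(obs) == 95
    assert (obs["period"] <= 2013).sum() == 70
    assert obs["period"].between(2014, 2018).sum() == 25
    assert sv.observed_cell_count((1997, 2017), dt.date(2018, 12, 31)) == 95


def test_mid_year_anniversary_rule_shrinks_observed_region():
    n = sv.observed_cell_count(
        (1997, 2017), dt.date(2018, 12, 31), anniversary_rule="mid_year"
    )
    assert n < 95  # period-2018 cells need follow-up into mid-2019


def test_monotone_at_risk_within_cohorts(sim_grid):
    for _, grp in sim_grid.observed.groupby("cohort"):
        at_risk = grp.sort_values("survivorship")["n_at_risk"].to_numpy()
        assert (np.diff(at_risk) <= 0).all()


def test_grid_csv_round_trip(sim_grid, tmp_path):
    path = tmp_path / "grid.csv"
    sim_grid.to_csv(path, header_lines=["provenance test"])
    back = sv.IntervalSurvivalGrid.from_csv(path)
    pd.testing.assert_frame_equal(
        back.cells[["survivorship", "cohort", "n_at_risk", "n_survived", "status"]],
        sim_grid.cells[["survivorship", "cohort", "n_at_risk", "n_survived", "status"]],
    )


def test_aggregation_equivalence(toy_records):
    """Grid from records equals grid ingested from its own aggregate counts."""
    grid = sv.build_interval_grid(toy_records, dt.date(2010, 1, 1))
    agg = grid.cells[["survivorship", "cohort", "n_at_risk", "n_survived"]]
    back = sv.ingest_aggregated_counts(agg)
    pd.testing.assert_frame_equal(back.cells, grid.cells)


def test_survivors_exceeding_at_risk_rejected():
    bad = pd.DataFrame(
        {"survivorship": [1], "cohort": [2000], "n_at_risk": [10], "n_survived": [12]}
    )
    with pytest.raises(GridError, match="n_survived > n_at_risk"):
        sv.ingest_aggregated_counts(bad)


def test_broken_chained_at_risk_names_cells():
    bad = pd.DataFrame(
        {
            "survivorship": [1, 2],
            "cohort": [2000, 2000],
            "n_at_risk": [10, 9],  # should be 8 = survivors of interval 1
            "n_survived": [8, 7],
        }
    )
    with pytest.raises(GridError, match=r"\(2, 2000\)"):
        sv.ingest_aggregated_counts(bad)


def test_registry_summary_counts_ingest_as_one_cohort():
    """The 2017 published stratum counts, summed, give 14,529 at risk."""
    from survcast.datasets import registry_summary

    row = registry_summary().loc[2017]
    total = int(row["male"] + row["female"])
    table = pd.DataFrame(
        {
            "survivorship": [1],
            "cohort": [2017],
            "n_at_risk": [total],
            "n_survived": [total // 2],
        }
    )
    grid = sv.ingest_aggregated_counts(table)
    assert grid.observed["n_at_risk"].iloc[0] == 14529


def test_empty_record_set_rejected():
    with pytest.raises(InputError, match="empty"):
        sv.build_interval_grid(pd.DataFrame(columns=["diagnosis_date"]), dt.date(2010, 1, 1))


def test_death_before_diagnosis_rejected():
    with pytest.raises(InputError, match="precedes diagnosis"):
        sv.PatientRecord(
            diagnosis_date=dt.date(2000, 9, 1), death_date=dt.date(2000, 1, 1)
        )


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 364 * 3),  # diagnosis offset within 3 cohort years
            st.one_of(st.none(), st.integers(0, 3650)),  # days to death
        ),
        min_size=1,
        max_size=40,
    )
)
def test_aggregation_equivalence_property(patients):
    """Patient-level and aggregate construction agree cell by cell."""
    base = dt.date(2000, 7, 1)
    records = []
    for diag_off, death_off in patients:
        diag = base + dt.timedelta(days=diag_off)
        death = diag + dt.timedelta(days=death_off) if death_off is not None else None
        records.append(sv.PatientRecord(diagnosis_date=diag, death_date=death))
    grid = sv.build_interval_grid(records, dt.date(2015, 1, 1))
    agg = grid.cells[["survivorship", "cohort", "n_at_risk", "n_survived"]]
    back = sv.ingest_aggregated_counts(agg)
    pd.testing.assert_frame_equal(back.cells, grid.cells)
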