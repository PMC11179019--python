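"""Relative survival against a matched general population (Ederer II).

Relative survival divides the cohort's observed interval survival by
the survival its members would have had under general-population
mortality matched on age, sex and calendar year.  The Ederer II
estimator conditions the expectation on the patients actually alive at
the start of each interval: the expected interval survival e(s, c) is
the at-risk-weighted mean of the matched annual survival probabilities
q(age, sex, year), with ages advanced one year per survivorship step
and the calendar year equal to the interval's period c + s.

The relative rate r(s,c)/e(s,c) may exceed 1 (patients outliving the
population); the 5-year relative survival is the product of the five
interval ratios, identically (prod r)/(prod e).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .lifetable import (
    AGE_GROUPS,
    IntervalSurvivalGrid,
    _records_frame,
    assign_cohort_year,
    interval_anniversary,
)

#: Representative single age used when only broad age groups are recorded.
AGE_GROUP_MIDPOINTS = {"<55": 50, "55-64": 60, "65-74": 70, ">=75": 80}


class PopulationLifeTable:
    """Annual survival probability q(age, sex, year) of the general population."""

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "year", "q"}
        missing = required - set(table.columns)
        if missing:
            raise InputError(f"life table missing columns {sorted(missing)}")
        t = table.copy()
        if ((t["q"] <= 0) | (t["q"] > 1)).any():
            raise InputError("life-table q values must lie in (0, 1]")
        self._q = {
            (int(a), s, int(y)): float(q)
            for a, s, y, q in zip(t["age"], t["sex"], t["year"], t["q"])
        }
        self.table = t

    def q(self, age: int, sex: str, year: int) -> float:
        key = (int(age), sex, int(year))
        try:
            return self._q[key]
        except KeyError:
            raise InputError(
                f"life table has no cell (age={age}, sex={sex}, year={year})"
            ) from None

    @classmethod
    def from_csv(cls, path) -> "PopulationLifeTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def expected_interval_survival(
    composition: pd.DataFrame,
    life_table: PopulationLifeTable,
    s: int,
    cohort: int,
) -> float:
    """Ederer-II expected survival for interval ``s`` of cohort ``cohort``.

    ``composition`` has columns ``age`` (age at diagnosis), ``sex`` and
    ``n`` (patients alive at the interval start).  Ages are advanced
    ``s - 1`` years and matched at calendar year ``cohort + s``.
    """
    required = {"age", "sex", "n"}
    if required - set(composition.columns):
        raise InputError("composition needs columns age, sex, n")
    n = composition["n"].to_numpy(float)
    if n.sum() <= 0:
        raise InputError("empty composition")
    qs = np.array(
        [
            life_table.q(int(a) + s - 1, sex, cohort + s)
            for a, sex in zip(composition["age"], composition["sex"])
        ]
    )
    return float(np.average(qs, weights=n))


def expected_grid(
    records: pd.DataFrame,
    life_table: PopulationLifeTable,
    grid: IntervalSurvivalGrid,
) -> pd.DataFrame:
    """Expected interval survival e(s, c) for every observed cell of ``grid``.

    The at-risk composition of each interval is taken from the records:
    patients of cohort c still alive at the interval-s start (per the
    grid's anniversary rule), grouped by age-group midpoint and sex.
    """
    df = _records_frame(records)
    df["cohort"] = df["diagnosis_date"].map(lambda d: assign_cohort_year(d.date()))
    df["age"] = df["age_group"].map(AGE_GROUP_MIDPOINTS)
    if df["age"].isna().any():
        raise InputError(f"age_group labels must be among {AGE_GROUPS}")
    rows = []
    for (s, cohort), _ in grid.observed.groupby(["survivorship", "cohort"]):
        s, cohort = int(s), int(cohort)
        sub = df[df["cohort"] == cohort]
        if s > 1:
            anniv = pd.Timestamp(
                interval_anniversary(cohort, s - 1, grid.anniversary_rule)
            )
            alive = sub["death_date"].isna() | (sub["death_date"] > anniv)
            sub = sub[alive]
        comp = (
            sub.groupby(["age", "sex"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        e = expected_interval_survival(comp, life_table, s, cohort)
        rows.append((s, cohort, cohort + s, e))
    return pd.DataFrame(rows, columns=["survivorship", "cohort", "period", "expected"])


def relative_rate(observed: float, expected: float) -> float:
    """Interval relative survival r/e; may exceed 1."""
    if expected <= 0:
        raise InputError("expected survival must be positive")
    return observed / expected


def relative_grid(
    grid: IntervalSurvivalGrid, expected: pd.DataFrame
) -> IntervalSurvivalGrid:
    """Grid whose rates are relative (r/e), counts rescaled to match.

    Survivor counts are rescaled to ``n_at_risk * r/e`` so downstream
    binomial fitting weights cells as before.  When any ratio exceeds
    1 - 1e-6 the logit link is inappropriate; the returned grid carries
    ``ratio_exceeds_one=True`` and callers should model on the log
    scale (``ModelConfig`` link or a log-transform fit).
    """
    cells = grid.cells.merge(
        expected, on=["survivorship", "cohort", "period"], how="left"
    )
    obs = cells["status"] == "observed"
    if cells.loc[obs, "expected"].isna().any():
        bad = cells.loc[obs & cells["expected"].isna(), ["survivorship", "cohort"]]
        raise InputError(
            f"expected survival missing for cells {bad.to_records(index=False).tolist()}"
        )
    cells.loc[obs, "rate"] = cells.loc[obs, "rate"] / cells.loc[obs, "expected"]
    cells.loc[obs, "n_survived"] = (
        cells.loc[obs, "n_at_risk"] * cells.loc[obs, "rate"]
    )
    out_cells = cells[grid.cells.columns]
    out = IntervalSurvivalGrid.__new__(IntervalSurvivalGrid)
    out.cells = out_cells.sort_values(["cohort", "survivorship"], ignore_index=True)
    out.anniversary_rule = grid.anniversary_rule
    out.ratio_exceeds_one = bool((cells.loc[obs, "rate"] > 1 - 1e-6).any())
    return out


class RelativeFit:
    """SPC-type fit of relative survival ratios on the log scale.

    Ratios can exceed 1, so instead of the binomial/logit GLM the model
    is weighted least squares of log(ratio) on the same SPC design
    (survivorship intercepts + drift + curvatures), weighted by the
    at-risk counts.  Extrapolation shares the spline tail-linearity
    guarantees of the absolute-survival model.
    """

    def __init__(self, design, params: np.ndarray):
        self.design = design
        self.params = params

    def predict_ratio(self, s, cohort) -> np.ndarray:
        return np.exp(self.design.matrix(np.atleast_1d(s), np.atleast_1d(cohort)) @ self.params)


def fit_relative(
    rel_grid: IntervalSurvivalGrid,
    n_knots_period: int = 5,
    n_knots_cohort: int = 5,
    constraint: str = "drop-period-linear",
) -> RelativeFit:
    """Fit the log-scale SPC model to a relative-survival grid."""
    from .spc import build_design

    design = build_design(rel_grid, n_knots_period, n_knots_cohort, constraint)
    s, cohort, n_at_risk, _ = rel_grid.counts()
    ratio = rel_grid.observed["rate"].to_numpy(float)
    if (ratio <= 0).any():
        raise InputError("relative rates must be positive for log-scale fitting")
    X = design.matrix(s, cohort)
    w = np.sqrt(n_at_risk)
    params, *_ = np.linalg.lstsq(X * w[:, None], np.log(ratio) * w, rcond=None)
    return RelativeFit(design, params)
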