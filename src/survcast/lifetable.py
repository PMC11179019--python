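"""Cohort life tables on the survivorship-period-cohort grid.

A diagnosis *cohort* ``c`` is a mid-year-to-mid-year block: patients
diagnosed in ``[July 1 of c, June 30 of c+1)``.  Follow-up is organised in
whole-year *survivorship* intervals ``s = 1..max_s``; the interval ``s``
for cohort ``c`` falls in calendar *period* ``p = c + s``.  The 1-year
interval survival rate ``r(s, c)`` is the fraction of patients alive at
the start of interval ``s`` who are still alive at its end.

Interval anniversaries are defined from the cohort block, not from each
patient's own diagnosis date.  Two conventions are supported:

``calendar_end`` (default)
    A patient survives interval ``s`` if still alive on December 31 of
    calendar year ``c + s``.  Since diagnosis dates are uniform over the
    mid-year block (mean ~ December 31 of year ``c``), this tracks one
    whole year of mean follow-up per interval, and a cell ``(s, c)`` is
    *observed* as soon as follow-up extends to December 31 of ``c + s``.

``mid_year``
    Anniversaries at June 30 of year ``c + s + 1`` (one year past the
    end of the cohort block), so every patient has a full ``s`` years of
    potential follow-up before the cell is called observed.

Only administrative censoring at the end of follow-up exists: registries
linked to national death records lose nobody, so a patient alive at the
follow-up end survives every complete interval.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GridError, InputError

SEXES = ("male", "female")
AGE_GROUPS = ("<55", "55-64", "65-74", ">=75")
HISTOLOGIES = ("ADENO", "SCC", "SCLC", "other")
STAGES = ("I", "II", "III", "IV", "unknown")

#: Cell status labels.
OBSERVED, FUTURE, DEGENERATE = "observed", "future", "degenerate"

GRID_COLUMNS = [
    "survivorship",
    "cohort",
    "period",
    "n_at_risk",
    "n_survived",
    "rate",
    "status",
]


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """One registry diagnosis with follow-up and stratum labels."""

    diagnosis_date: dt.date
    death_date: dt.date | None = None
    sex: str = "male"
    age_group: str = "65-74"
    histology: str = "ADENO"
    stage: str = "unknown"

    def __post_init__(self) -> None:
        if self.death_date is not None and self.death_date < self.diagnosis_date:
            raise InputError(
                f"death date {self.death_date} precedes diagnosis {self.diagnosis_date}"
            )
        for value, allowed, name in (
            (self.sex, SEXES, "sex"),
            (self.age_group, AGE_GROUPS, "age_group"),
            (self.histology, HISTOLOGIES, "histology"),
            (self.stage, STAGES, "stage"),
        ):
            if value not in allowed:
                raise InputError(f"{name}={value!r} not in {allowed}")


def assign_cohort_year(
    diagnosis_date: dt.date,
    cohort_range: tuple[int, int] | None = None,
) -> int:
    """Map a diagnosis date to its mid-year diagnosis cohort.

    Dates in ``[July 1 of y, June 30 of y+1]`` belong to cohort ``y``.
    If ``cohort_range`` is given, dates mapping outside it are rejected.
    """
    y = diagnosis_date.year
    cohort = y if diagnosis_date.month >= 7 else y - 1
    if cohort_range is not None and not cohort_range[0] <= cohort <= cohort_range[1]:
        raise InputError(
            f"diagnosis {diagnosis_date} falls in cohort {cohort}, outside the "
            f"study window {cohort_range[0]}-{cohort_range[1]}"
        )
    return cohort


def interval_anniversary(cohort: int, s: int, rule: str = "calendar_end") -> dt.date:
    """Date by which a cohort-``cohort`` patient must be alive to survive interval ``s``."""
    if rule == "calendar_end":
        return dt.date(cohort + s, 12, 31)
    if rule == "mid_year":
        return dt.date(cohort + s + 1, 6, 30)
    raise InputError(f"unknown anniversary rule {rule!r}")


class IntervalSurvivalGrid:
    """At-risk / survivor counts and rates on the (survivorship, cohort) grid.

    Backed by a tidy DataFrame with one row per cell and columns
    ``survivorship, cohort, period, n_at_risk, n_survived, rate, status``.
    ``period = cohort + survivorship`` always.  Cells whose follow-up is
    incomplete carry status ``future`` and NaN counts; cells with nobody
    at risk are ``degenerate`` and excluded from model fitting.
    """

    def __init__(self, cells: pd.DataFrame, anniversary_rule: str = "calendar_end"):
        missing = [c for c in GRID_COLUMNS if c not in cells.columns]
        if missing:
            raise GridError(f"grid table missing columns {missing}")
        cells = cells[GRID_COLUMNS].copy()
        for col in ("n_at_risk", "n_survived", "rate"):
            cells[col] = cells[col].astype(float)
        for col in ("survivorship", "cohort", "period"):
            cells[col] = cells[col].astype(int)
        cells = cells.sort_values(["cohort", "survivorship"], ignore_index=True)
        self.cells = cells
        self.anniversary_rule = anniversary_rule
        self._check_invariants()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame | Iterable[PatientRecord],
        follow_up_end: dt.date,
        max_s: int = 5,
        cohort_range: tuple[int, int] | None = None,
        anniversary_rule: str = "calendar_end",
    ) -> "IntervalSurvivalGrid":
        return build_interval_grid(
            records, follow_up_end, max_s, cohort_range, anniversary_rule
        )

    # -- invariants --------------------------------------------------------

    def _check_invariants(self) -> None:
        df = self.cells
        if df.duplicated(["survivorship", "cohort"]).any():
            raise GridError("duplicate (survivorship, cohort) cells")
        if not (df["period"] == df["cohort"] + df["survivorship"]).all():
            raise GridError("period != cohort + survivorship in some cells")
        obs = df[df["status"] != FUTURE]
        bad = obs[obs["n_survived"] > obs["n_at_risk"]]
        if len(bad):
            cells = [(int(r.survivorship), int(r.cohort)) for r in bad.itertuples()]
            raise GridError(f"n_survived > n_at_risk in cells {cells}")
        # chained at-risk: survivors of interval s are at risk in s+1
        for cohort, grp in obs.groupby("cohort"):
            grp = grp.sort_values("survivorship")
            s_vals = grp["survivorship"].to_numpy()
            consecutive = s_vals[1:] == s_vals[:-1] + 1
            nxt = grp["n_at_risk"].to_numpy()[1:]
            cur = grp["n_survived"].to_numpy()[:-1]
            mismatched = consecutive & (nxt != cur)
            if mismatched.any():
                at = [(int(s), int(cohort)) for s in s_vals[1:][mismatched]]
                raise GridError(
                    f"chained at-risk invariant violated entering cells {at}: "
                    "n_at_risk(s+1,c) must equal n_survived(s,c)"
                )

    # -- access ------------------------------------------------------------

    @property
    def observed(self) -> pd.DataFrame:
        """Observed, fittable cells (excludes future and degenerate)."""
        return self.cells[self.cells["status"] == OBSERVED]

    @property
    def cohorts(self) -> np.ndarray:
        return np.sort(self.cells["cohort"].unique())

    @property
    def max_s(self) -> int:
        return int(self.cells["survivorship"].max())

    def rate(self, s: int, cohort: int) -> float:
        sel = self.cells[
            (self.cells["survivorship"] == s) & (self.cells["cohort"] == cohort)
        ]
        if sel.empty:
            raise GridError(f"no cell (s={s}, cohort={cohort})")
        return float(sel["rate"].iloc[0])

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(s, cohort, n_at_risk, n_survived) arrays over observed cells."""
        obs = self.observed
        return (
            obs["survivorship"].to_numpy(int),
            obs["cohort"].to_numpy(int),
            obs["n_at_risk"].to_numpy(float),
            obs["n_survived"].to_numpy(float),
        )

    def with_counts(self, n_survived: np.ndarray) -> "IntervalSurvivalGrid":
        """Grid with observed survivor counts replaced (chained at-risk rebuilt).

        Used by the bootstrap: ``n_survived`` is aligned with
        ``self.observed`` rows (sorted by cohort then survivorship), and
        the at-risk count of each subsequent interval is reset to the new
        survivor count of the previous one.
        """
        cells = self.cells.copy()
        idx = cells.index[cells["status"] == OBSERVED]
        if len(idx) != len(n_survived):
            raise GridError("replacement counts misaligned with observed cells")
        cells.loc[idx, "n_survived"] = np.asarray(n_survived, float)
        for cohort, grp in cells.loc[idx].groupby("cohort"):
            grp = grp.sort_values("survivorship")
            rows = grp.index.to_numpy()
            s_vals = grp["survivorship"].to_numpy()
            for i in range(1, len(rows)):
                if s_vals[i] == s_vals[i - 1] + 1:
                    cells.loc[rows[i], "n_at_risk"] = cells.loc[
                        rows[i - 1], "n_survived"
                    ]
        with np.errstate(invalid="ignore", divide="ignore"):
            cells.loc[idx, "rate"] = (
                cells.loc[idx, "n_survived"] / cells.loc[idx, "n_at_risk"]
            )
        zero = cells.loc[idx, "n_at_risk"] == 0
        cells.loc[idx[zero], "status"] = DEGENERATE
        return IntervalSurvivalGrid(cells, self.anniversary_rule)

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path_or_buf, header_lines: Sequence[str] = ()) -> None:
        out = self.cells.copy()
        out["rate"] = out["rate"].map(
            lambda r: "" if pd.isna(r) else format(r, ".6g")
        )
        buf = io.StringIO()
        for line in header_lines:
            buf.write(f"# {line}\n")
        out.to_csv(buf, index=False)
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path, anniversary_rule: str = "calendar_end") -> "IntervalSurvivalGrid":
        df = pd.read_csv(path, comment="#")
        return ingest_aggregated_counts(df, anniversary_rule)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_obs = int((self.cells["status"] == OBSERVED).sum())
        return (
            f"<IntervalSurvivalGrid cohorts {self.cohorts.min()}-{self.cohorts.max()}"
            f", {n_obs} observed cells>"
        )


def _records_frame(records: pd.DataFrame | Iterable[PatientRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        raise InputError("empty record set")
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    if "death_date" in df.columns:
        df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")
    else:
        df["death_date"] = pd.NaT
    return df


def build_interval_grid(
    records: pd.DataFrame | Iterable[PatientRecord],
    follow_up_end: dt.date | str,
    max_s: int = 5,
    cohort_range: tuple[int, int] | None = None,
    anniversary_rule: str = "calendar_end",
) -> IntervalSurvivalGrid:
    """Aggregate patient records into the interval-survival grid.

    Parameters
    ----------
    records
        DataFrame with ``diagnosis_date`` and optional ``death_date``
        columns (ISO dates), or an iterable of :class:`PatientRecord`.
    follow_up_end
        Last date with complete death ascertainment.  Cells whose
        anniversary falls after it are flagged ``future``.
    max_s
        Number of survivorship intervals (5 for 5-year survival).
    cohort_range
        Inclusive ``(first, last)`` diagnosis cohorts; defaults to the
        range present in the data.  Records outside it are rejected.
    """
    df = _records_frame(records)
    follow_up_end = pd.Timestamp(follow_up_end)

    cohorts = df["diagnosis_date"].map(
        lambda d: assign_cohort_year(d.date(), cohort_range)
    )
    if follow_up_end.date() < df["diagnosis_date"].max().date():
        raise InputError("follow_up_end precedes the latest diagnosis date")

    c_min, c_max = (
        cohort_range if cohort_range is not None else (cohorts.min(), cohorts.max())
    )

    # Index of the interval in which each patient dies (inf = never observed
    # to die).  A death after anniversary(s) counts as surviving interval s.
    rows = []
    for cohort in range(int(c_min), int(c_max) + 1):
        in_cohort = cohorts == cohort
        n0 = int(in_cohort.sum())
        deaths = df.loc[in_cohort, "death_date"]
        death_interval = np.full(n0, np.inf)
        for s in range(max_s, 0, -1):
            anniv = pd.Timestamp(interval_anniversary(cohort, s, anniversary_rule))
            death_interval[(deaths <= anniv).to_numpy()] = s
        at_risk = n0
        for s in range(1, max_s + 1):
            anniv = interval_anniversary(cohort, s, anniversary_rule)
            observed = follow_up_end.date() >= anniv
            if not observed:
                rows.append((s, cohort, cohort + s, np.nan, np.nan, np.nan, FUTURE))
                continue
            survived = int((death_interval > s).sum())
            status = OBSERVED if at_risk > 0 else DEGENERATE
            rate = survived / at_risk if at_risk > 0 else np.nan
            rows.append((s, cohort, cohort + s, at_risk, survived, rate, status))
            at_risk = survived
    grid = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return IntervalSurvivalGrid(grid, anniversary_rule)


def ingest_aggregated_counts(
    table: pd.DataFrame | str,
    anniversary_rule: str = "calendar_end",
) -> IntervalSurvivalGrid:
    """Build a grid from pre-aggregated cell counts.

    ``table`` is a DataFrame or CSV path with columns ``survivorship``
    (or ``s``), ``cohort``, ``n_at_risk`` and ``n_survived``; ``period``,
    ``rate`` and ``status`` are recomputed.  The chained at-risk
    invariant is enforced, so a grid written with
    :meth:`IntervalSurvivalGrid.to_csv` round-trips exactly.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, comment="#")
    df = table.rename(columns={"s": "survivorship"}).copy()
    required = {"survivorship", "cohort", "n_at_risk", "n_survived"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"aggregate table missing columns {sorted(missing)}")
    if "status" in df.columns:
        future = df["status"] == FUTURE
    else:
        future = pd.Series(False, index=df.index)
    df["period"] = df["cohort"] + df["survivorship"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rate"] = df["n_survived"] / df["n_at_risk"]
    df["status"] = np.where(
        future, FUTURE, np.where(df["n_at_risk"] > 0, OBSERVED, DEGENERATE)
    )
    df.loc[future, ["n_at_risk", "n_survived", "rate"]] = np.nan
    return IntervalSurvivalGrid(df[GRID_COLUMNS], anniversary_rule)


def observed_cell_count(
    cohort_range: tuple[int, int],
    follow_up_end: dt.date,
    max_s: int = 5,
    anniversary_rule: str = "calendar_end",
) -> int:
    """Closed-form size of the observed (triangular) grid region."""
    c0, c1 = cohort_range
    total = 0
    for cohort in range(c0, c1 + 1):
        for s in range(1, max_s + 1):
            if follow_up_end >= interval_anniversary(cohort, s, anniversary_rule):
                total += 1
    return total


def read_registry(path) -> pd.DataFrame:
    """Read a registry CSV (diagnosis_date, death_date, sex, age_group, histology, stage)."""
    df = pd.read_csv(path, comment="#", dtype={"death_date": "string"})
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    df["death_date"] = pd.to_datetime(df.get("death_date"), errors="coerce")
    for col, allowed in (
        ("sex", SEXES),
        ("age_group", AGE_GROUPS),
        ("histology", HISTOLOGIES),
        ("stage", STAGES),
    ):
        if col in df.columns:
            bad = set(df[col].dropna().unique()) - set(allowed)
            if bad:
                raise InputError(f"registry column {col} has unknown labels {sorted(bad)}")
    return df
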