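"""Holdout validation (sMAPE) and bootstrap confidence intervals.

Validation mimics real forecasting: the model is fitted to cells whose
calendar period falls at or before a split year and judged on the cells
after it with the symmetric mean absolute percentage error,

    sMAPE = (100 / n) * sum |F - A| / ((|A| + |F|) / 2),

a scale-free accuracy measure bounded in [0, 200].

Uncertainty comes from a parametric-flavoured nonparametric bootstrap on
the aggregate grid: within each replicate every observed cell's survivor
count is redrawn Binomial(n_at_risk, observed rate), the chained at-risk
counts are rebuilt so the grid invariant holds, the model is refitted
and the target statistics recomputed; percentile intervals (2.5th and
97.5th) across replicates give the 95% CI.  Cell-level resampling works
on deidentified aggregate data; a patient-level variant (resampling
records with replacement within each cohort) is available when records
are supplied.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import FitError, InputError
from .forecast import five_year_survival
from .lifetable import IntervalSurvivalGrid, build_interval_grid
from .spc import ModelConfig, SPCFit, build_design, fit_spc, predict_surface

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ValidationSplit:
    """Training = periods <= split_year, validation = periods after it."""

    split_year: int = 2013


@dataclasses.dataclass
class ValidationReport:
    smape: float
    split_year: int
    n_training: int
    n_validation: int
    table: pd.DataFrame  # survivorship, cohort, period, actual, predicted
    smape_variant: str = "divide-by-mean"


@dataclasses.dataclass
class BootstrapResult:
    targets: list
    point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    replicates: np.ndarray  # (B, n_targets)
    B: int
    seed: int
    unit: str
    n_failures: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [str(t) for t in self.targets],
                "point": self.point,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def smape(actual, forecast) -> float:
    """Symmetric mean absolute percentage error, divide-by-mean form (in %)."""
    a = np.asarray(actual, float)
    f = np.asarray(forecast, float)
    if a.shape != f.shape or a.ndim != 1 or len(a) == 0:
        raise InputError("actual and forecast must be equal-length nonempty vectors")
    denom = (np.abs(a) + np.abs(f)) / 2.0
    if np.any(denom == 0):
        raise InputError("sMAPE undefined for a pair with |actual| + |forecast| = 0")
    return float(100.0 * np.mean(np.abs(f - a) / denom))


def split_grid(grid: IntervalSurvivalGrid, split: ValidationSplit):
    """Partition observed cells into training/validation by period."""
    obs = grid.observed
    periods = obs["period"]
    if split.split_year < periods.min() or split.split_year >= periods.max():
        raise InputError(
            f"split year {split.split_year} outside the observed period range "
            f"{int(periods.min())}-{int(periods.max())}"
        )
    train = obs[periods <= split.split_year]
    valid = obs[periods > split.split_year]
    return train, valid


def validate(
    grid: IntervalSurvivalGrid,
    config: ModelConfig | None = None,
    split: ValidationSplit = ValidationSplit(),
) -> ValidationReport:
    """Fit on the training periods, forecast the held-out cells, report sMAPE."""
    config = config or ModelConfig()
    train, valid = split_grid(grid, split)
    if valid.empty:
        raise InputError("validation region is empty")
    train_cells = grid.cells.copy()
    is_valid = train_cells["period"] > split.split_year
    train_cells.loc[is_valid, ["n_at_risk", "n_survived", "rate"]] = np.nan
    train_cells.loc[is_valid, "status"] = "future"
    train_grid = IntervalSurvivalGrid(train_cells, grid.anniversary_rule)

    design = build_design(
        train_grid, config.n_knots_period, config.n_knots_cohort, config.constraint
    )
    fit = fit_spc(design, train_grid, config)
    predicted = fit.predict_rate(
        valid["survivorship"].to_numpy(), valid["cohort"].to_numpy()
    )
    table = pd.DataFrame(
        {
            "survivorship": valid["survivorship"].to_numpy(int),
            "cohort": valid["cohort"].to_numpy(int),
            "period": valid["period"].to_numpy(int),
            "actual": valid["rate"].to_numpy(),
            "predicted": predicted,
        }
    )
    return ValidationReport(
        smape=smape(table["actual"], table["predicted"]),
        split_year=split.split_year,
        n_training=len(train),
        n_validation=len(valid),
        table=table,
    )


def _s5_targets(
    grid: IntervalSurvivalGrid,
    fit: SPCFit,
    cohorts: list[int],
    horizon_cohort: int,
    horizon_period: int,
) -> np.ndarray:
    surface = predict_surface(fit, grid, horizon_cohort, horizon_period)
    return np.array(
        [
            five_year_survival(surface, c, grid=grid, max_s=grid.max_s)[0]
            for c in cohorts
        ]
    )


def bootstrap_ci(
    grid: IntervalSurvivalGrid,
    config: ModelConfig | None = None,
    cohorts: list[int] | None = None,
    cells: list[tuple[int, int]] | None = None,
    B: int = 10_000,
    seed: int = 0,
    records: pd.DataFrame | None = None,
    unit: str = "aggregate",
    max_failure_rate: float = 0.01,
) -> BootstrapResult:
    """Percentile bootstrap CIs for S5(cohort) values and/or cell rates.

    Targets: ``cohorts`` yields 5-year survival per listed cohort
    (observed factors where available, model factors elsewhere, as in
    the headline forecasts); ``cells`` yields predicted interval rates
    r(s, c).  ``unit`` selects cell-level binomial resampling
    ("aggregate", default) or patient-level resampling with replacement
    within cohorts ("patient", requires ``records``).
    """
    if B < 2:
        raise InputError("need at least 2 bootstrap replicates")
    if not cohorts and not cells:
        raise InputError("no bootstrap targets given")
    if unit not in ("aggregate", "patient"):
        raise InputError(f"unknown resampling unit {unit!r}")
    if unit == "patient" and records is None:
        raise InputError("patient-level resampling requires records")
    config = config or ModelConfig()
    cohorts = list(cohorts or [])
    cells = [tuple(map(int, c)) for c in (cells or [])]
    horizon_cohort = max(
        [config.horizon_cohort]
        + cohorts
        + [c for _, c in cells]
    )
    horizon_period = max(
        [config.horizon_period]
        + [c + grid.max_s for c in cohorts]
        + [s + c for s, c in cells]
    )

    def statistics(g: IntervalSurvivalGrid) -> np.ndarray:
        design = build_design(
            g, config.n_knots_period, config.n_knots_cohort, config.constraint
        )
        fit = fit_spc(design, g, config)
        out = []
        if cohorts:
            out.append(_s5_targets(g, fit, cohorts, horizon_cohort, horizon_period))
        if cells:
            out.append(
                fit.predict_rate(
                    np.array([s for s, _ in cells]), np.array([c for _, c in cells])
                )
            )
        return np.concatenate(out)

    point = statistics(grid)
    rng = np.random.default_rng(seed)

    reps = np.empty((B, len(point)))
    failures = 0
    if unit == "aggregate":
        runner = _AggregateBootstrap(grid, config, cohorts, cells)
        for b in range(B):
            try:
                reps[b] = runner.replicate(rng)
            except FitError as exc:
                failures += 1
                reps[b] = np.nan
                logger.warning("bootstrap replicate %d failed: %s", b, exc)
    else:
        rec = records.copy()
        rec_cohorts = pd.to_datetime(rec["diagnosis_date"]).map(
            lambda d: d.year if d.month >= 7 else d.year - 1
        )
        groups = {c: g.index.to_numpy() for c, g in rec.groupby(rec_cohorts)}
        fu_end = _follow_up_end_of(grid)
        for b in range(B):
            try:
                take = np.concatenate(
                    [rng.choice(ix, size=len(ix), replace=True) for ix in groups.values()]
                )
                g = build_interval_grid(
                    rec.loc[take],
                    fu_end,
                    max_s=grid.max_s,
                    anniversary_rule=grid.anniversary_rule,
                )
                reps[b] = statistics(g)
            except FitError as exc:
                failures += 1
                reps[b] = np.nan
                logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if failures > max_failure_rate * B:
        raise FitError(
            f"{failures}/{B} bootstrap replicates failed to fit "
            f"(> {max_failure_rate:.0%} allowed)"
        )
    ok = ~np.isnan(reps).any(axis=1)
    lo, hi = np.nanpercentile(reps[ok], [2.5, 97.5], axis=0)
    targets = [("s5", c) for c in cohorts] + [("rate",) + c for c in cells]
    return BootstrapResult(
        targets=targets,
        point=point,
        ci_low=lo,
        ci_high=hi,
        replicates=reps,
        B=B,
        seed=seed,
        unit=unit,
        n_failures=failures,
    )


class _AggregateBootstrap:
    """Vectorised cell-level bootstrap engine.

    The resampled grids share the original cell coordinates, so the
    design matrix, knots and detrending projections are fixed; only the
    binomial endog changes between replicates.  Chained redraws, the
    refit and the target statistics all run on preallocated arrays.
    """

    def __init__(self, grid, config: ModelConfig, cohorts, cells):
        import statsmodels.api as sm

        from .spc import LINKS

        self.config = config
        self.cohorts = cohorts
        self.cells = cells
        obs = grid.observed.sort_values(["cohort", "survivorship"])
        self.s = obs["survivorship"].to_numpy(int)
        self.c = obs["cohort"].to_numpy(int)
        self.n_at_risk0 = obs["n_at_risk"].to_numpy(float)
        self.rates = obs["rate"].to_numpy(float)
        self.n = len(obs)
        index = {(int(s), int(c)): i for i, (s, c) in enumerate(zip(self.s, self.c))}
        # previous-interval row (chained at-risk) or -1 where absent
        self.prev = np.array(
            [index.get((s - 1, c), -1) for s, c in zip(self.s, self.c)]
        )
        self.s_order = np.sort(np.unique(self.s))
        self.rows_by_s = {s: np.where(self.s == s)[0] for s in self.s_order}

        self.design = build_design(
            grid, config.n_knots_period, config.n_knots_cohort, config.constraint
        )
        self.X = self.design.matrix(self.s, self.c)
        self.family = sm.families.Binomial(link=LINKS[config.link]())
        self.link = LINKS[config.link]()
        self.max_s = grid.max_s

        # target bookkeeping: S5 factors come from the resampled grid when
        # observed, from the refit surface otherwise
        self.factor_obs_row = {}
        pred_cells = []
        for c in cohorts:
            for s in range(1, self.max_s + 1):
                key = (s, int(c))
                if key in index:
                    self.factor_obs_row[key] = index[key]
                else:
                    pred_cells.append(key)
        pred_cells += [cell for cell in cells]
        self.pred_cells = pred_cells
        if pred_cells:
            self.X_pred = self.design.matrix(
                np.array([s for s, _ in pred_cells]),
                np.array([c for _, c in pred_cells]),
            )

    def replicate(self, rng: np.random.Generator) -> np.ndarray:
        import statsmodels.api as sm

        survived = np.zeros(self.n)
        at_risk = np.zeros(self.n)
        for s in self.s_order:
            rows = self.rows_by_s[s]
            prev = self.prev[rows]
            at_risk[rows] = np.where(
                prev >= 0, survived[np.maximum(prev, 0)], self.n_at_risk0[rows]
            )
            n_int = at_risk[rows].astype(np.int64)
            survived[rows] = rng.binomial(n_int, self.rates[rows])
        died = at_risk - survived
        succ, fail = survived, died
        if self.config.separation == "continuity":
            sat = (survived == at_risk) | (survived == 0)
            eps = self.config.separation_eps
            succ = survived + eps * sat
            fail = died + eps * sat
        keep = at_risk > 0
        endog = np.column_stack([succ[keep], fail[keep]])
        try:
            res = sm.GLM(endog, self.X[keep], family=self.family).fit(
                maxiter=self.config.max_iter, tol=self.config.tol
            )
        except Exception as exc:
            raise FitError(f"bootstrap refit failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise FitError("non-finite bootstrap refit parameters")
        pred_rate = {}
        if self.pred_cells:
            vals = self.link.inverse(self.X_pred @ res.params)
            pred_rate = dict(zip(self.pred_cells, vals))
        out = []
        for c in self.cohorts:
            s5 = 1.0
            for s in range(1, self.max_s + 1):
                key = (s, int(c))
                if key in self.factor_obs_row:
                    i = self.factor_obs_row[key]
                    s5 *= survived[i] / at_risk[i] if at_risk[i] > 0 else np.nan
                else:
                    s5 *= pred_rate[key]
            out.append(s5)
        for cell in self.cells:
            out.append(pred_rate[cell])
        return np.asarray(out)


def _follow_up_end_of(grid: IntervalSurvivalGrid):
    """Latest anniversary among observed cells — the effective follow-up end."""
    from .lifetable import interval_anniversary

    obs = grid.observed
    return max(
        interval_anniversary(int(c), int(s), grid.anniversary_rule)
        for s, c in zip(obs["survivorship"], obs["cohort"])
    )
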