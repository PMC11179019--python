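"""The survivorship-period-cohort (SPC) model.

Interval survival rates r(s, c) live on a grid where survivorship s,
diagnosis cohort c and calendar period p are exactly collinear
(p = c + s), the survival analogue of the classical age-period-cohort
identification problem.  Individual linear effects of period and cohort
are therefore not identifiable, but two things are:

* the *net drift* — the sum of the period and cohort linear slopes; and
* the *curvatures* — the slope-free nonlinear parts of the period and
  cohort effects.

The model fitted here is a binomial GLM on cell counts,

    link r(s,c) = a_s + delta * drift_axis + g_p(p) + g_c(c),

with a_s a separate intercept per survivorship year, delta the net
drift attached to one axis (the identification constraint), and g_p,
g_c restricted-cubic-spline curvature functions whose columns are
orthogonalised against their axis's constant and linear trends.  Both
constraints ("drop-period-linear" attaches drift to cohort,
"drop-cohort-linear" to period) span the same column space, so fitted
and predicted rates are constraint-invariant — the property the test
suite enforces.

Extrapolation keeps the observed net drift and extends the curvature
functions beyond their boundary knots, where restricted cubic splines
are linear by construction; future rates therefore continue the
observed slopes, bending only as much as the observed curvature
implies.
"""

from __future__ import annotations

import dataclasses
import logging
import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._splines import DetrendedSpline, rcs_knots
from .errors import FitError, InputError
from .lifetable import IntervalSurvivalGrid

logger = logging.getLogger(__name__)

DROP_PERIOD = "drop-period-linear"
DROP_COHORT = "drop-cohort-linear"
LINKS = {"logit": sm.families.links.Logit, "cloglog": sm.families.links.CLogLog}


@dataclasses.dataclass
class ModelConfig:
    """Tunable choices for the SPC fit.

    n_knots_period, n_knots_cohort
        Restricted-cubic-spline knots per axis, placed at equally
        spaced quantiles of the observed axis values.
    link
        "logit" (default) or "cloglog" for the binomial GLM.
    constraint
        Which collinear linear term is dropped for identification;
        immaterial to fitted/predicted rates.
    separation
        Haldane continuity correction applied to all-survivor or
        all-death cells: "continuity" adds ``separation_eps`` successes
        and failures to such cells, "none" leaves them (the GLM may
        then run coefficients to infinity).
    horizon_cohort, horizon_period
        Default extrapolation limits for :func:`predict_surface`.
    """

    n_knots_period: int = 5
    n_knots_cohort: int = 5
    link: str = "logit"
    constraint: str = DROP_PERIOD
    separation: str = "continuity"
    separation_eps: float = 0.5
    horizon_cohort: int = 2020
    horizon_period: int = 2025
    max_iter: int = 100
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise InputError(f"unknown link {self.link!r}; choose from {sorted(LINKS)}")
        if self.constraint not in (DROP_PERIOD, DROP_COHORT):
            raise InputError(f"unknown constraint {self.constraint!r}")


@dataclasses.dataclass
class SPCDesign:
    """Frozen design: survivorship coding, drift axis, curvature bases."""

    s_levels: np.ndarray
    constraint: str
    cohort_ref: float
    period_ref: float
    period_spline: DetrendedSpline | None
    cohort_spline: DetrendedSpline | None
    column_names: list[str]

    def matrix(self, s: np.ndarray, cohort: np.ndarray) -> np.ndarray:
        """Evaluate the design at arbitrary (s, cohort) cells."""
        s = np.asarray(s, int)
        cohort = np.asarray(cohort, float)
        period = cohort + s
        cols = [np.ones_like(cohort)]
        for level in self.s_levels[1:]:
            cols.append((s == level).astype(float))
        if self.constraint == DROP_PERIOD:
            cols.append(cohort - self.cohort_ref)
        else:
            cols.append(period - self.period_ref)
        if self.period_spline is not None:
            cols.append(self.period_spline(period))
        if self.cohort_spline is not None:
            cols.append(self.cohort_spline(cohort))
        return np.column_stack(cols)

    @property
    def n_params(self) -> int:
        return len(self.column_names)


@dataclasses.dataclass
class SPCFit:
    """A converged SPC fit: coefficients plus the fitted rate surface."""

    design: SPCDesign
    config: ModelConfig
    params: np.ndarray
    cov_params: np.ndarray
    deviance: float
    n_iter: int
    fitted: pd.DataFrame  # survivorship, cohort, period, rate

    def linpred(self, s: np.ndarray, cohort: np.ndarray) -> np.ndarray:
        return self.design.matrix(s, cohort) @ self.params

    def predict_rate(self, s: np.ndarray, cohort: np.ndarray) -> np.ndarray:
        link = LINKS[self.config.link]()
        return link.inverse(self.linpred(s, cohort))


def build_design(
    grid: IntervalSurvivalGrid,
    n_knots_period: int = 5,
    n_knots_cohort: int = 5,
    constraint: str = DROP_PERIOD,
) -> SPCDesign:
    """Construct the SPC design from the observed region of a grid.

    Curvature knots sit at quantiles of the observed cell values of each
    axis, so they are always interior to the observed range and the
    spline tails (hence all extrapolation) begin at the data boundary.
    """
    obs = grid.observed
    if obs.empty:
        raise InputError("grid has no observed cells")
    s_levels = np.sort(obs["survivorship"].unique())
    for level in s_levels:
        if not (obs["survivorship"] == level).any():
            raise InputError(f"no observed cells at survivorship {level}")
    period = obs["period"].to_numpy(float)
    cohort = obs["cohort"].to_numpy(float)
    # n_knots = 0 drops the curvature basis for that axis (drift-only model)
    period_spline = (
        DetrendedSpline(period, rcs_knots(period, n_knots_period))
        if n_knots_period
        else None
    )
    cohort_spline = (
        DetrendedSpline(cohort, rcs_knots(cohort, n_knots_cohort))
        if n_knots_cohort
        else None
    )
    drift_name = "cohort_linear" if constraint == DROP_PERIOD else "period_linear"
    names = (
        ["intercept"]
        + [f"s{int(l)}" for l in s_levels[1:]]
        + [drift_name]
        + [
            f"period_curv{i+1}"
            for i in range(period_spline.n_cols if period_spline else 0)
        ]
        + [
            f"cohort_curv{i+1}"
            for i in range(cohort_spline.n_cols if cohort_spline else 0)
        ]
    )
    return SPCDesign(
        s_levels=s_levels,
        constraint=constraint,
        cohort_ref=float(cohort.mean()),
        period_ref=float(period.mean()),
        period_spline=period_spline,
        cohort_spline=cohort_spline,
        column_names=names,
    )


def fit_spc(
    design: SPCDesign,
    grid: IntervalSurvivalGrid,
    config: ModelConfig | None = None,
) -> SPCFit:
    """Maximum-likelihood binomial fit of the SPC model to observed cells."""
    config = config or ModelConfig(constraint=design.constraint)
    s, cohort, n_at_risk, n_survived = grid.counts()
    if len(s) == 0:
        raise InputError("no observed cells to fit")
    n_died = n_at_risk - n_survived

    saturated = (n_survived == n_at_risk) | (n_survived == 0)
    if saturated.any():
        if config.separation == "continuity":
            eps = config.separation_eps
            logger.warning(
                "continuity correction (+%g/+%g) applied to %d all-survivor or "
                "all-death cells",
                eps,
                eps,
                int(saturated.sum()),
            )
            n_survived = n_survived + eps * saturated
            n_died = n_died + eps * saturated

    X = design.matrix(s, cohort)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"design matrix rank deficient ({rank} < {X.shape[1]}); "
            "reduce knots or survivorship levels"
        )
    family = sm.families.Binomial(link=LINKS[config.link]())
    model = sm.GLM(np.column_stack([n_survived, n_died]), X, family=family)
    try:
        res = model.fit(maxiter=config.max_iter, tol=config.tol)
    except Exception as exc:  # statsmodels raises PerfectSeparation etc.
        raise FitError(f"GLM fit failed: {exc}") from exc
    if not res.converged:
        raise FitError(
            f"IRLS did not converge in {config.max_iter} iterations "
            f"(last deviance {res.deviance:.6g})"
        )
    if not np.isfinite(res.deviance):
        raise FitError("non-finite deviance after fit")
    fitted = pd.DataFrame(
        {
            "survivorship": s,
            "cohort": cohort,
            "period": cohort + s,
            "rate": res.fittedvalues,
        }
    )
    return SPCFit(
        design=design,
        config=config,
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        deviance=float(res.deviance),
        n_iter=int(res.fit_history["iteration"]),
        fitted=fitted,
    )


def fit_grid(
    grid: IntervalSurvivalGrid, config: ModelConfig | None = None
) -> SPCFit:
    """Convenience wrapper: build the design from the grid, then fit."""
    config = config or ModelConfig()
    design = build_design(
        grid, config.n_knots_period, config.n_knots_cohort, config.constraint
    )
    return fit_spc(design, grid, config)


def predict_surface(
    fit: SPCFit,
    grid: IntervalSurvivalGrid,
    horizon_cohort: int | None = None,
    horizon_period: int | None = None,
) -> pd.DataFrame:
    """Fitted + extrapolated rate surface out to the requested horizons.

    Covers every (s, cohort) with cohort from the first observed cohort
    through ``horizon_cohort`` and period <= ``horizon_period``.  Cells
    inside the fitted region carry provenance ``fitted``; all others
    ``extrapolated``.
    """
    horizon_cohort = horizon_cohort or fit.config.horizon_cohort
    horizon_period = horizon_period or fit.config.horizon_period
    obs = grid.observed
    c_min = int(obs["cohort"].min())
    c_obs_max = int(obs["cohort"].max())
    p_obs_max = int(obs["period"].max())
    if horizon_cohort < c_obs_max or horizon_period < p_obs_max:
        raise InputError(
            f"horizon (cohort {horizon_cohort}, period {horizon_period}) below the "
            f"observed maxima (cohort {c_obs_max}, period {p_obs_max})"
        )
    s_levels = fit.design.s_levels
    cells = [
        (int(s), c, c + int(s))
        for c in range(c_min, horizon_cohort + 1)
        for s in s_levels
        if c + s <= horizon_period
    ]
    surf = pd.DataFrame(cells, columns=["survivorship", "cohort", "period"])
    surf["rate"] = fit.predict_rate(
        surf["survivorship"].to_numpy(), surf["cohort"].to_numpy()
    )
    observed_keys = set(zip(obs["survivorship"].astype(int), obs["cohort"].astype(int)))
    surf["provenance"] = [
        "fitted" if (s, c) in observed_keys else "extrapolated"
        for s, c in zip(surf["survivorship"], surf["cohort"])
    ]
    return surf


def decompose_effects(fit: SPCFit) -> dict:
    """Estimable pieces of the fit: net drift and the two curvature series.

    The net drift (sum of period and cohort linear slopes per year) is
    identifiable because the saturated survivorship intercepts absorb
    the reparameterisation between constraints; the individual period
    and cohort slopes are not, and are reported only as attached to the
    constraint axis.  Curvatures are estimable outright.
    """
    design = fit.design
    names = design.column_names
    idx = {name: i for i, name in enumerate(names)}
    drift_name = "cohort_linear" if design.constraint == DROP_PERIOD else "period_linear"
    drift = float(fit.params[idx[drift_name]])

    obs = fit.fitted
    periods = np.sort(obs["period"].unique())
    cohorts = np.sort(obs["cohort"].unique())
    p_cols = [idx[n] for n in names if n.startswith("period_curv")]
    c_cols = [idx[n] for n in names if n.startswith("cohort_curv")]
    period_curv = (
        design.period_spline(periods) @ fit.params[p_cols]
        if design.period_spline is not None
        else np.zeros(len(periods))
    )
    cohort_curv = (
        design.cohort_spline(cohorts) @ fit.params[c_cols]
        if design.cohort_spline is not None
        else np.zeros(len(cohorts))
    )
    return {
        "net_drift": drift,
        "constraint": design.constraint,
        "period_curvature": pd.Series(period_curv, index=periods, name="period_curvature"),
        "cohort_curvature": pd.Series(cohort_curv, index=cohorts, name="cohort_curvature"),
        "survivorship_intercepts": {
            int(l): float(
                fit.params[idx["intercept"]]
                + (fit.params[idx[f"s{int(l)}"]] if f"s{int(l)}" in idx else 0.0)
            )
            for l in design.s_levels
        },
    }
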