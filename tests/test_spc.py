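"""SPC model: design construction, fitting, invariance, extrapolation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import survcast as sv
from survcast._splines import DetrendedSpline, rcs_basis, rcs_knots
from survcast.errors import InputError
from survcast.spc import DROP_COHORT, DROP_PERIOD


# ---------------------------------------------------------------- splines


def test_spline_tails_are_exactly_linear():
    knots = np.array([2.0, 4.0, 6.0, 8.0])
    x_left = np.array([-5.0, -4.0, -3.0, -2.0])
    x_right = np.array([10.0, 11.0, 12.0, 13.0])
    for x in (x_left, x_right):
        B = rcs_basis(x, knots)
        second_diff = np.diff(B, n=2, axis=0)
        assert np.abs(second_diff).max() <= 1e-9


def test_detrended_columns_have_zero_slope():
    x = np.arange(1998.0, 2019.0)
    spline = DetrendedSpline(x, rcs_knots(x, 5))
    B = spline(x)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, B, rcond=None)
    assert np.abs(coef[1]).max() < 1e-10  # slope row


def test_detrending_preserves_tail_linearity():
    x = np.arange(1998.0, 2019.0)
    spline = DetrendedSpline(x, rcs_knots(x, 5))
    beyond = np.arange(2020.0, 2030.0)
    assert np.abs(np.diff(spline(beyond), n=2, axis=0)).max() <= 1e-9


def test_too_few_axis_values_for_knots():
    with pytest.raises(InputError, match="too few distinct"):
        rcs_knots(np.array([1.0, 2.0]), 5)


# ----------------------------------------------------------------- design


def test_design_full_rank_on_registry_range(sim_grid):
    design = sv.build_design(sim_grid, 5, 5)
    X = design.matrix(*sim_grid.counts()[:2])
    assert np.linalg.matrix_rank(X) == X.shape[1]
    # 5 survivorship levels -> intercept + 4 indicators
    assert sum(n.startswith("s") for n in design.column_names) == 4


# -------------------------------------------------------------------- fit


def test_constant_rate_recovered():
    """No trends, true rate 0.8, large counts: every fitted rate near 0.8."""
    cohorts = range(2000, 2012)
    rows = []
    rng = np.random.default_rng(5)
    for c in cohorts:
        n = 20_000
        for s in range(1, 6):
            surv = rng.binomial(n, 0.8)
            rows.append((s, c, n, surv))
            n = surv
    grid = sv.ingest_aggregated_counts(
        pd.DataFrame(rows, columns=["survivorship", "cohort", "n_at_risk", "n_survived"])
    )
    fit = sv.fit_grid(grid)
    assert np.abs(fit.fitted["rate"] - 0.8).max() < 0.01


def test_saturated_two_cell_fit_matches_observed():
    """Intercept + drift on two cells of one survivorship level is saturated."""
    grid = sv.ingest_aggregated_counts(
        pd.DataFrame(
            {
                "survivorship": [1, 1],
                "cohort": [2000, 2001],
                "n_at_risk": [100, 200],
                "n_survived": [60, 150],
            }
        )
    )
    design = sv.build_design(grid, 0, 0)
    fit = sv.fit_spc(design, grid, sv.ModelConfig(n_knots_period=0, n_knots_cohort=0))
    assert fit.fitted["rate"].to_numpy() == pytest.approx([0.6, 0.75], abs=1e-8)


def test_constraint_invariance_on_fitted_and_predicted(sim_grid):
    """The module's central property: identification choice never moves rates."""
    fits = {}
    for constraint in (DROP_PERIOD, DROP_COHORT):
        cfg = sv.ModelConfig(constraint=constraint)
        fits[constraint] = sv.fit_grid(sim_grid, cfg)
    surf = {
        k: sv.predict_surface(f, sim_grid, 2020, 2025) for k, f in fits.items()
    }
    a, b = surf[DROP_PERIOD], surf[DROP_COHORT]
    logit = lambda p: np.log(p / (1 - p))
    assert np.abs(
        logit(a["rate"].to_numpy()) - logit(b["rate"].to_numpy())
    ).max() <= 1e-8
    assert not np.allclose(fits[DROP_PERIOD].params, fits[DROP_COHORT].params)


def test_linear_truth_extrapolates_linearly(drift_surface, scenario):
    """Pure-drift truth: predicted logits continue the line beyond the data."""
    grid = sv.exact_grid(drift_surface, scenario)
    fit = sv.fit_grid(grid)
    surface = sv.predict_surface(fit, grid, 2020, 2025)
    pred = surface[surface["survivorship"] == 1].sort_values("cohort")
    eta = np.log(pred["rate"] / (1 - pred["rate"]))
    true_eta = drift_surface.logit_rate(
        np.ones(len(pred), int), pred["cohort"].to_numpy()
    )
    assert np.abs(eta.to_numpy() - true_eta).max() < 1e-6


def test_registry_range_extrapolation_counts(sim_fit, sim_grid):
    surface = sv.predict_surface(sim_fit, sim_grid, 2020, 2025)
    assert (surface["provenance"] == "extrapolated").sum() == 25
    assert (surface["provenance"] == "fitted").sum() == 95
    assert surface["rate"].between(0, 1, inclusive="neither").all()


def test_horizon_below_observed_range_rejected(sim_fit, sim_grid):
    with pytest.raises(InputError, match="below the observed maxima"):
        sv.predict_surface(sim_fit, sim_grid, 2010, 2025)


def test_fitted_cells_match_surface(sim_fit, sim_grid):
    surface = sv.predict_surface(sim_fit, sim_grid, 2020, 2025)
    merged = surface.merge(
        sim_fit.fitted,
        on=["survivorship", "cohort", "period"],
        suffixes=("_surf", "_fit"),
    )
    assert np.abs(merged["rate_surf"] - merged["rate_fit"]).max() < 1e-12


# ------------------------------------------------------------- decompose


def test_decompose_null_model():
    rows = []
    for c in range(2000, 2012):
        n = 50_000
        for s in range(1, 6):
            surv = round(n * 0.8)
            rows.append((s, c, n, surv))
            n = surv
    grid = sv.ingest_aggregated_counts(
        pd.DataFrame(rows, columns=["survivorship", "cohort", "n_at_risk", "n_survived"])
    )
    fit = sv.fit_grid(grid)
    effects = sv.decompose_effects(fit)
    assert abs(effects["net_drift"]) < 1e-3
    assert np.abs(effects["period_curvature"]).max() < 1e-3
    assert np.abs(effects["cohort_curvature"]).max() < 1e-3


def test_pure_cohort_drift_recovered_under_both_constraints(scenario):
    b = 0.05
    surf = sv.TrueSurface(a_s=np.array([0.2, 0.9, 1.4, 1.8, 2.2]), drift=b)
    grid = sv.exact_grid(surf, scenario)
    for constraint in (DROP_PERIOD, DROP_COHORT):
        fit = sv.fit_grid(grid, sv.ModelConfig(constraint=constraint))
        assert sv.decompose_effects(fit)["net_drift"] == pytest.approx(b, abs=1e-4)


def test_curvatures_constraint_invariant(sim_grid):
    effects = {
        c: sv.decompose_effects(sv.fit_grid(sim_grid, sv.ModelConfig(constraint=c)))
        for c in (DROP_PERIOD, DROP_COHORT)
    }
    for key in ("period_curvature", "cohort_curvature"):
        diff = effects[DROP_PERIOD][key] - effects[DROP_COHORT][key]
        assert np.abs(diff).max() <= 1e-8


# ----------------------------------------------------------------- oracle


def binomial_deviance(n, y, mu):
    """Saturated-vs-model deviance for binomial counts."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n * (1 - mu))), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def test_deviance_matches_brute_force_mle():
    """Generic optimizer on the same design reaches the same deviance."""
    scen = sv.ScenarioConfig(
        cohort_start=2000,
        cohort_end=2009,
        size_start=2000,
        size_end=4000,
        follow_up_end=dt.date(2020, 1, 1),
        max_s=3,
    )
    surf = sv.TrueSurface(
        a_s=np.array([0.3, 0.9, 1.5, 1.8, 2.1]),
        drift=0.04,
        cohort_ref=2005.0,
        cohort_curvature=sv.rcs_curvature((2002.0, 2005.0, 2008.0), (0.2,), (2000, 2009)),
    )
    grid = sv.simulate_grid(surf, scen, seed=42)
    assert len(grid.observed) == 30
    design = sv.build_design(grid, 3, 3)
    fit = sv.fit_spc(design, grid)

    s, c, n, y = grid.counts()
    X = design.matrix(s, c)

    def negll(beta):
        eta = X @ beta
        mu = expit(eta)
        return -np.sum(y * np.log(mu) + (n - y) * np.log1p(-mu))

    def grad(beta):
        mu = expit(X @ beta)
        return X.T @ (n * mu - y)

    res = minimize(negll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    oracle_dev = binomial_deviance(n, y, expit(X @ res.x))
    assert abs(fit.deviance - oracle_dev) < 1e-6


# ------------------------------------------------------------- separation


def test_all_survivor_level_triggers_continuity_correction(caplog):
    rows = []
    for c in range(2000, 2010):
        n = 500
        for s in range(1, 4):
            surv = n if s == 3 else int(n * 0.8)
            rows.append((s, c, n, surv))
            n = surv
    grid = sv.ingest_aggregated_counts(
        pd.DataFrame(rows, columns=["survivorship", "cohort", "n_at_risk", "n_survived"])
    )
    import logging

    with caplog.at_level(logging.WARNING, logger="survcast.spc"):
        fit = sv.fit_grid(grid, sv.ModelConfig(n_knots_period=3, n_knots_cohort=3))
    assert "continuity correction" in caplog.text
    assert fit.fitted["rate"].between(0, 1, inclusive="neither").all()
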