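"""Cohort-approach 5-year survival, stratum mixing, counterfactual mixes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survcast as sv
from survcast.errors import InputError
from survcast.forecast import ALL_OBSERVED, ALL_PREDICTED, MIXED


def surface_from_factors(cohort, factors):
    return pd.DataFrame(
        {
            "survivorship": range(1, len(factors) + 1),
            "cohort": cohort,
            "period": [cohort + s for s in range(1, len(factors) + 1)],
            "rate": factors,
            "provenance": "extrapolated",
        }
    )


@pytest.mark.parametrize(
    "factors, expected",
    [
        ([1.0] * 5, 1.0),
        ([0.5] * 5, 0.03125),
        ([0.9, 0.8, 0.7, 0.6, 0.5], 0.1512),
    ],
)
def test_five_year_product(factors, expected):
    surf = surface_from_factors(2020, factors)
    s5, flag = sv.five_year_survival(surf, 2020)
    assert s5 == pytest.approx(expected, rel=1e-12)
    assert flag == ALL_PREDICTED


def test_product_bounded_by_every_factor_and_log_additive():
    rng = np.random.default_rng(0)
    factors = rng.uniform(0.3, 0.99, size=5)
    surf = surface_from_factors(2020, factors)
    s5, _ = sv.five_year_survival(surf, 2020)
    assert s5 <= factors.min()
    assert np.log(s5) == pytest.approx(np.sum(np.log(factors)), abs=1e-12)


def test_missing_factor_names_cells():
    surf = surface_from_factors(2020, [0.9, 0.8, 0.7])
    with pytest.raises(InputError, match=r"\(4, 2020\)"):
        sv.five_year_survival(surf, 2020)


def test_composition_flags_follow_observation_boundary(sim_grid, sim_fit):
    """Follow-up to 2018: cohorts <=2013 all-observed, 2014-2017 mixed,
    2018-2020 all-predicted."""
    surface = sv.predict_surface(sim_fit, sim_grid, 2020, 2025)
    table = sv.forecast_table(sim_grid, surface).set_index("cohort")
    comp = table["composition"]
    assert (comp.loc[1997:2013] == ALL_OBSERVED).all()
    assert (comp.loc[2014:2017] == MIXED).all()
    assert (comp.loc[2018:2020] == ALL_PREDICTED).all()


def test_single_stratum_weight_is_identity():
    t = pd.DataFrame(
        {"cohort": [2019, 2020], "s5": [0.3, 0.4], "composition": "all-predicted",
         "ci_low": np.nan, "ci_high": np.nan}
    )
    out = sv.weighted_forecast({"only": t}, sv.StratumWeights({"only": 1.0}))
    assert out["s5"].tolist() == [0.3, 0.4]


def test_two_strata_arithmetic_mean():
    mk = lambda v: pd.DataFrame(
        {"cohort": [2020], "s5": [v], "composition": "all-predicted",
         "ci_low": np.nan, "ci_high": np.nan}
    )
    out = sv.weighted_forecast(
        {"a": mk(0.2), "b": mk(0.4)}, sv.StratumWeights({"a": 0.5, "b": 0.5})
    )
    assert out["s5"].iloc[0] == pytest.approx(0.3)


def test_weight_for_missing_stratum_rejected():
    t = pd.DataFrame(
        {"cohort": [2020], "s5": [0.3], "composition": "all-predicted",
         "ci_low": np.nan, "ci_high": np.nan}
    )
    with pytest.raises(InputError, match="absent strata"):
        sv.weighted_forecast({"a": t}, sv.StratumWeights({"a": 0.5, "b": 0.5}))


def test_weighted_forecast_matches_pooled_for_homogeneous_strata(surface):
    """Sex strata with identical true surfaces: the 2017-weights average of
    per-stratum forecasts agrees with the pooled forecast."""
    scen_m = sv.default_scenario(size_start=4041, size_end=8008)
    scen_f = sv.default_scenario(size_start=1721, size_end=6521)
    tables = {}
    for key, scen, seed in (("male", scen_m, 11), ("female", scen_f, 12)):
        grid = sv.simulate_grid(surface, scen, seed=seed)
        fit = sv.fit_grid(grid)
        tables[key] = sv.forecast_table(grid, sv.predict_surface(fit, grid, 2020, 2025))
    weights = sv.StratumWeights({"male": 8008, "female": 6521}, reference_year=2017)
    mixed = sv.weighted_forecast(tables, weights).set_index("cohort")
    pooled_true = surface.s5(2020)
    assert mixed.loc[2020, "s5"] == pytest.approx(pooled_true, abs=0.02)


def test_counterfactual_identity_and_constant_cases():
    years = [2007, 2008, 2009]
    rates = pd.DataFrame(
        {"I": [0.6, 0.6, 0.6], "IV": [0.1, 0.1, 0.1]}, index=years
    )
    mix = sv.StratumWeights({"I": 0.2, "IV": 0.8}, reference_year=2007)
    series = sv.counterfactual_fixed_mix(rates, mix)
    # stage rates constant over years -> counterfactual constant
    assert series.nunique() == 1
    assert series.iloc[0] == pytest.approx(0.2 * 0.6 + 0.8 * 0.1)


def test_counterfactual_flat_when_only_mix_shifts():
    """Stage-specific rates fixed while the mix moves to earlier stages:
    the factual weighted series rises, the fixed-2007-mix series is flat."""
    years = list(range(2007, 2013))
    r_I, r_IV = 0.6, 0.1
    rates = pd.DataFrame({"I": r_I, "IV": r_IV}, index=years)
    shares_I = np.linspace(0.15, 0.40, len(years))
    factual = shares_I * r_I + (1 - shares_I) * r_IV
    mix_2007 = sv.StratumWeights({"I": shares_I[0], "IV": 1 - shares_I[0]}, 2007)
    counter = sv.counterfactual_fixed_mix(rates, mix_2007)
    assert np.ptp(counter.to_numpy()) < 1e-12
    assert factual[-1] > counter.iloc[-1] + 0.1
    # identity: using each year's own mix reproduces the factual series
    for year, share in zip(years, shares_I):
        w = sv.StratumWeights({"I": share, "IV": 1 - share}, year)
        assert sv.counterfactual_fixed_mix(rates.loc[[year]], w).iloc[
            0
        ] == pytest.approx(share * r_I + (1 - share) * r_IV)


def test_bundled_counts_as_stratum_weights():
    from survcast import datasets

    w = datasets.stratum_weights(2017, "histology")
    assert sum(w.weights.values()) == pytest.approx(1.0)
    assert w.weights["ADENO"] == pytest.approx(10223 / 14529, abs=1e-9)
    with pytest.raises(InputError, match="unavailable"):
        datasets.stratum_weights(2000, "stage")  # staging not recorded yet


def test_misaligned_stage_series_rejected():
    rates = pd.DataFrame({"I": [0.6, np.nan], "IV": [0.1, 0.1]}, index=[2007, 2008])
    with pytest.raises(InputError, match="misaligned"):
        sv.counterfactual_fixed_mix(rates, sv.StratumWeights({"I": 0.5, "IV": 0.5}))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
def test_five_year_product_bound_property(factors):
    surf = surface_from_factors(2020, factors)
    s5, _ = sv.five_year_survival(surf, 2020)
    assert 0 <= s5 <= min(factors) + 1e-15
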