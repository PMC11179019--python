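"""5-year survival by the cohort approach, stratum mixing, counterfactuals.

The cohort-approach 5-year survival of diagnosis cohort c is the product
of its five 1-year interval survival rates,

    S5(c) = r(1,c) * r(2,c) * r(3,c) * r(4,c) * r(5,c),

each factor taken from the observed grid when its cell is observed and
from the model surface otherwise.  A cohort is labelled "all-observed"
(every factor observed), "mixed", or "all-predicted".
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .lifetable import OBSERVED, IntervalSurvivalGrid

ALL_OBSERVED, MIXED, ALL_PREDICTED = "all-observed", "mixed", "all-predicted"

FORECAST_COLUMNS = ["cohort", "s5", "composition", "ci_low", "ci_high"]


@dataclasses.dataclass
class StratumWeights:
    """Nonnegative stratum weights summing to 1, tied to a reference year."""

    weights: dict[str, float]
    reference_year: int | None = None

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), float)
        if (vals < 0).any():
            raise InputError("stratum weights must be nonnegative")
        total = vals.sum()
        if total <= 0:
            raise InputError("stratum weights sum to zero")
        if not np.isclose(total, 1.0):
            self.weights = {k: v / total for k, v in self.weights.items()}

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], reference_year: int | None = None
    ) -> "StratumWeights":
        return cls({k: float(v) for k, v in counts.items()}, reference_year)


def _factor_lookup(grid: IntervalSurvivalGrid | None, surface: pd.DataFrame | None):
    obs: dict[tuple[int, int], float] = {}
    pred: dict[tuple[int, int], float] = {}
    if grid is not None:
        g = grid.observed
        obs = {
            (int(s), int(c)): float(r)
            for s, c, r in zip(g["survivorship"], g["cohort"], g["rate"])
        }
    if surface is not None:
        pred = {
            (int(s), int(c)): float(r)
            for s, c, r in zip(
                surface["survivorship"], surface["cohort"], surface["rate"]
            )
        }
    return obs, pred


def five_year_survival(
    source: IntervalSurvivalGrid | pd.DataFrame,
    cohort: int,
    grid: IntervalSurvivalGrid | None = None,
    max_s: int = 5,
) -> tuple[float, str]:
    """S5(cohort) with its composition flag.

    ``source`` is a prediction surface (DataFrame) or a grid; when a
    surface is given, an optional ``grid`` supplies observed factors,
    which take precedence over predicted ones cell by cell.
    """
    if isinstance(source, IntervalSurvivalGrid):
        obs, pred = _factor_lookup(source, None)
    else:
        obs, pred = _factor_lookup(grid, source)
    factors, provenance, missing = [], [], []
    for s in range(1, max_s + 1):
        key = (s, int(cohort))
        if key in obs:
            factors.append(obs[key])
            provenance.append("observed")
        elif key in pred:
            factors.append(pred[key])
            provenance.append("predicted")
        else:
            missing.append(key)
    if missing:
        raise InputError(f"missing interval factors for cells {missing}")
    s5 = float(np.prod(factors))
    n_obs = provenance.count("observed")
    flag = ALL_OBSERVED if n_obs == max_s else ALL_PREDICTED if n_obs == 0 else MIXED
    return s5, flag


def forecast_table(
    grid: IntervalSurvivalGrid | None,
    surface: pd.DataFrame,
    cohorts: list[int] | None = None,
    max_s: int = 5,
) -> pd.DataFrame:
    """ForecastTable: S5 and composition per cohort (CI columns empty)."""
    if cohorts is None:
        counts = surface.groupby("cohort")["survivorship"].count()
        cohorts = [int(c) for c in counts.index[counts >= max_s]]
    rows = []
    for c in cohorts:
        s5, flag = five_year_survival(surface, c, grid=grid, max_s=max_s)
        rows.append((c, s5, flag, np.nan, np.nan))
    return pd.DataFrame(rows, columns=FORECAST_COLUMNS)


def weighted_forecast(
    stratum_forecasts: Mapping[str, pd.DataFrame],
    weights: StratumWeights,
) -> pd.DataFrame:
    """Weighted average of stratum-specific S5 series, cohort by cohort."""
    missing = set(weights.weights) - set(stratum_forecasts)
    if missing:
        raise InputError(f"weights given for absent strata {sorted(missing)}")
    tables = {k: stratum_forecasts[k].set_index("cohort") for k in weights.weights}
    axes = [tuple(t.index) for t in tables.values()]
    if len(set(axes)) != 1:
        raise InputError("stratum forecast tables do not share a cohort axis")
    cohorts = list(axes[0])
    s5 = sum(w * tables[k]["s5"] for k, w in weights.weights.items())
    comps = pd.DataFrame({k: tables[k]["composition"] for k in tables})
    composition = comps.apply(
        lambda row: row.iloc[0] if row.nunique() == 1 else MIXED, axis=1
    )
    out = pd.DataFrame(
        {
            "cohort": cohorts,
            "s5": s5.to_numpy(),
            "composition": composition.to_numpy(),
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
    )
    return out


def counterfactual_fixed_mix(
    stage_rates: pd.DataFrame,
    fixed_mix: StratumWeights,
) -> pd.Series:
    """Yearly survival had the stage mix stayed at its reference-year level.

    ``stage_rates`` has one row per year and one column per stage
    (survival rates); the result is the fixed-mix weighted average per
    year, the counterfactual trend used to gauge how much of an observed
    improvement is attributable to a shifting stage distribution (e.g.
    screening moving diagnoses to earlier stages) rather than to
    stage-specific gains.
    """
    missing = set(fixed_mix.weights) - set(stage_rates.columns)
    if missing:
        raise InputError(f"stage series missing for strata {sorted(missing)}")
    sub = stage_rates[list(fixed_mix.weights)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise InputError(f"stage rate series misaligned: missing values at years {bad}")
    w = pd.Series(fixed_mix.weights)
    out = sub.mul(w, axis=1).sum(axis=1)
    out.name = "counterfactual_s5"
    return out


def write_forecast_csv(table: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, float_format="%.6g")
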