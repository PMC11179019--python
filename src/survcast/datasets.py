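"""Bundled reference tables.

``registry_summary()`` loads the published annual diagnosis counts of
lung cancer in Taiwan (1997-2017) by sex, age group, histology and
stage — the stratum-mix trajectories the default synthetic scenario
mirrors and the source of default stratum weights.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import InputError

_SUMMARY = "taiwan_lung_registry_summary.csv"

HISTOLOGY_COLUMNS = {"ADENO": "adeno", "SCC": "scc", "SCLC": "sclc", "other": "other"}
STAGE_COLUMNS = {"I": "stage_i", "II": "stage_ii", "III": "stage_iii", "IV": "stage_iv"}
SEX_COLUMNS = {"male": "male", "female": "female"}
AGE_COLUMNS = {
    "<55": "age_lt55",
    "55-64": "age_55_64",
    "65-74": "age_65_74",
    ">=75": "age_ge75",
}


#: Study-level diagnosis counts by sex as published in the source report.
#: The per-year table sums to 204,956 — 148 short of these study totals, an
#: internal inconsistency of the published figures that we preserve as is.
STUDY_SEX_TOTALS = {"male": 128_928, "female": 76_176}


def registry_summary() -> pd.DataFrame:
    """Annual stratum counts, indexed by diagnosis year."""
    path = resources.files("survcast.data").joinpath(_SUMMARY)
    with path.open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("year")


def study_total_diagnoses() -> int:
    """Published overall study size (sum of the published sex totals)."""
    return sum(STUDY_SEX_TOTALS.values())


def total_diagnoses(summary: pd.DataFrame | None = None) -> int:
    """All diagnoses over the covered years (sums the yearly sex counts)."""
    df = registry_summary() if summary is None else summary
    return int(df["male"].sum() + df["female"].sum())


def histology_share(year: int, histology: str, summary: pd.DataFrame | None = None) -> float:
    """Share of a histological type among all diagnoses of ``year``."""
    df = registry_summary() if summary is None else summary
    col = HISTOLOGY_COLUMNS.get(histology)
    if col is None:
        raise InputError(f"unknown histology {histology!r}")
    return float(df.loc[year, col] / df.loc[year, "total"])


def stage_share(year: int, stage: str, summary: pd.DataFrame | None = None) -> float:
    """Share of a stage among *staged* diagnoses of ``year``.

    Published stage percentages use staged patients as the denominator
    (stage-unknown cases are excluded), so this does too.
    """
    df = registry_summary() if summary is None else summary
    col = STAGE_COLUMNS.get(stage)
    if col is None:
        raise InputError(f"unknown stage {stage!r}")
    staged = df.loc[year, list(STAGE_COLUMNS.values())].sum()
    if pd.isna(staged) or staged == 0:
        raise InputError(f"no stage counts available for {year}")
    return float(df.loc[year, col] / staged)


def stratum_weights(year: int, dimension: str, summary: pd.DataFrame | None = None):
    """Observed stratum counts of ``year`` as normalised weights."""
    from .forecast import StratumWeights

    df = registry_summary() if summary is None else summary
    columns = {
        "sex": SEX_COLUMNS,
        "age_group": AGE_COLUMNS,
        "histology": HISTOLOGY_COLUMNS,
        "stage": STAGE_COLUMNS,
    }.get(dimension)
    if columns is None:
        raise InputError(f"unknown stratum dimension {dimension!r}")
    counts = {label: df.loc[year, col] for label, col in columns.items()}
    if any(pd.isna(v) for v in counts.values()):
        raise InputError(f"{dimension} counts unavailable for {year}")
    return StratumWeights.from_counts(counts, reference_year=year)
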