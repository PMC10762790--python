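"""From microdata to the analysis's sufficient statistic.

Three steps turn person-year records into model inputs:

1. population-weighted national quintiles of the area deprivation score
   (each quintile holding ~20% of the population);
2. selection of each person's most recent qualifying census form per
   follow-up year (rolling census design);
3. aggregation of survey-weighted deaths and exposures by single year of
   age x sex x quintile, pooled over follow-up years, with an all-quintile
   margin.

The counts table is the sufficient statistic of the Poisson rate model:
everything downstream (smoothing, calibration, life tables, rate ratios)
depends on the microdata only through it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import SEXES

#: Quintile code of the pooled (all-deprivation-levels) margin in counts tables.
ALL = 0

QUINTILES = (1, 2, 3, 4, 5)


def assign_quintiles(areas: pd.DataFrame) -> pd.DataFrame:
    """Assign each area a population-weighted deprivation quintile.

    Areas are sorted by ascending score (ties kept contiguous by a stable
    sort on ``area_id``); cumulative-population breakpoints at 20/40/60/80%
    of the national population define the quintiles.  An area straddling a
    breakpoint is assigned the quintile of the interval containing its
    population midpoint, which makes the assignment deterministic and
    independent of how the straddle is split.

    Returns a DataFrame with columns ``area_id``, ``quintile`` (1 = least
    deprived), one row per area, in the input row order.
    """
    if len(areas) == 0:
        raise ValueError("area table is empty")
    total = areas["population"].sum()
    if total <= 0:
        raise ValueError("total area population must be positive")
    srt = areas.sort_values(["score", "area_id"], kind="stable")
    pop = srt["population"].to_numpy(dtype=float)
    midpoint = np.cumsum(pop) - pop / 2.0
    quintile = np.clip(np.floor(midpoint / total * 5.0).astype(int) + 1, 1, 5)
    out = pd.DataFrame({"area_id": srt["area_id"].to_numpy(), "quintile": quintile})
    return areas[["area_id"]].merge(out, on="area_id")


def quintile_population_shares(areas: pd.DataFrame, assignment: pd.DataFrame) -> pd.Series:
    """Population share of each quintile (fractions summing to 1)."""
    merged = areas.merge(assignment, on="area_id")
    shares = merged.groupby("quintile")["population"].sum() / merged["population"].sum()
    return shares.reindex(QUINTILES, fill_value=0.0)


def select_census_form(
    person_history: pd.DataFrame, followup_year: int, window: int
):
    """Most recent qualifying census form for one person and follow-up year.

    A form with year ``c`` qualifies when ``followup_year - window < c <=
    followup_year``.  Returns the ``area_id`` of the most recent qualifying
    form, or ``None`` when no form qualifies (the person is excluded from
    that follow-up year).  Two forms in the same census year are malformed
    input and raise.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    years = person_history["census_year"]
    if years.duplicated().any():
        raise ValueError("multiple census forms in the same year for one person")
    ok = person_history[(years > followup_year - window) & (years <= followup_year)]
    if len(ok) == 0:
        return None
    return ok.loc[ok["census_year"].idxmax(), "area_id"]


def resolve_census_forms(
    forms: pd.DataFrame, followup_years, window: int
) -> pd.DataFrame:
    """Vectorised form selection for many persons and follow-up years.

    ``forms`` has columns ``person_id``, ``census_year``, ``area_id``.
    Returns one row per (person, follow-up year) with a qualifying form:
    ``person_id``, ``followup_year``, ``census_year``, ``area_id``.  Persons
    with no qualifying form for a year are absent from that year.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if forms.duplicated(["person_id", "census_year"]).any():
        raise ValueError("multiple census forms in the same year for one person")
    out = []
    for y in followup_years:
        ok = forms[(forms["census_year"] > y - window) & (forms["census_year"] <= y)]
        latest = (
            ok.sort_values(["person_id", "census_year"], kind="stable")
            .groupby("person_id", as_index=False)
            .tail(1)
        )
        latest = latest.assign(followup_year=y)
        out.append(latest[["person_id", "followup_year", "census_year", "area_id"]])
    return pd.concat(out, ignore_index=True)


def attach_quintiles(records: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Join quintile labels onto person-year records via ``area_id``."""
    merged = records.merge(assignment, on="area_id", how="left")
    if merged["quintile"].isna().any():
        missing = merged.loc[merged["quintile"].isna(), "area_id"].unique()[:5]
        raise ValueError(f"records reference areas without a quintile, e.g. {list(missing)}")
    return merged


def aggregate_counts(records: pd.DataFrame, age_range=(18, 100)) -> pd.DataFrame:
    """Survey-weighted deaths and exposures by age x sex x quintile.

    Records below the minimum age are dropped (an adult-mortality table);
    ages above the maximum are pooled into the terminal age.  Deaths are
    ``sum(weight * died)`` and exposure is ``sum(weight)`` per cell — a
    person dying in a year still counts fully in that year's population.
    The grid is completed with zero-filled cells, and an all-quintile
    margin (quintile code ``ALL`` = 0) is added per (age, sex).
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    if (records["weight"] < 0).any():
        raise ValueError("negative survey weights")
    min_age, max_age = age_range
    rec = records[records["age"] >= min_age].copy()
    if len(rec) == 0:
        raise ValueError("no records within the age range")
    rec["age"] = np.minimum(rec["age"].to_numpy(), max_age)
    rec["wdied"] = rec["weight"] * rec["died"]
    g = (
        rec.groupby(["age", "sex", "quintile"], observed=True)
        .agg(deaths=("wdied", "sum"), exposure=("weight", "sum"))
        .reset_index()
    )
    ages = np.arange(min_age, max_age + 1)
    grid = pd.MultiIndex.from_product(
        [ages, SEXES, QUINTILES], names=["age", "sex", "quintile"]
    )
    full = (
        g.set_index(["age", "sex", "quintile"])
        .reindex(grid, fill_value=0.0)
        .reset_index()
    )
    margin = (
        full.groupby(["age", "sex"], as_index=False)[["deaths", "exposure"]]
        .sum()
        .assign(quintile=ALL)
    )
    out = pd.concat([full, margin[full.columns]], ignore_index=True)
    return out.sort_values(["sex", "quintile", "age"], kind="stable").reset_index(drop=True)


def counts_slice(counts: pd.DataFrame, sex: str, quintile: int) -> pd.DataFrame:
    """One stratum of a counts table, sorted by age."""
    s = counts[(counts["sex"] == sex) & (counts["quintile"] == quintile)]
    if len(s) == 0:
        raise KeyError(f"no counts for sex={sex!r}, quintile={quintile}")
    return s.sort_values("age").reset_index(drop=True)
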