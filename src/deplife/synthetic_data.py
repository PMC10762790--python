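"""Synthetic census-linked mortality microdata with known ground truth.

Real deprivation-specific life tables are built from confidential
longitudinal samples that link census forms (carrying an area-level
deprivation score) to civil death records.  This module emulates such a
sample so that every downstream stage — quintile assignment, weighted
aggregation, P-spline smoothing, calibration, life tables, rate ratios —
can be validated against a hazard model whose parameters are known.

The generative model is a Gompertz–Makeham baseline hazard per sex with
proportional quintile effects, piecewise constant over single years of
age::

    mu(age, sex, q) = (c + a_sex * exp(b_sex * age)) * exp(log_hr[q])

Each individual is followed over a short run of calendar years.  In every
follow-up year an alive individual dies with probability ``1 - exp(-mu)``
(the exact one-year death probability under a hazard held constant within
the year) and, if dead, emits no records in later years.  Survey weights
are lognormal, rescaled to mean 1 within each census-year stratum, mimicking
design weights of a rolling census.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Proportional-hazard gradient used by default: a moderate, monotone
#: mortality gradient from the least (q1) to the most (q5) deprived quintile.
DEFAULT_QUINTILE_HR = (1.0, 1.15, 1.30, 1.50, 2.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_individuals:
        Number of individuals entering follow-up in the first year.
    seed:
        Seed for all randomness in :func:`simulate_microdata`.
    gompertz_a:
        Baseline hazard level per sex (hazard scale at age 0), per year.
    gompertz_b:
        Log-hazard slope per year of age, per sex.  Must be positive.
    makeham_c:
        Age-constant additive hazard component (background mortality).
    quintile_log_hr:
        Log hazard ratios of the five deprivation quintiles; the first
        entry (least deprived, the reference) must be 0.
    followup_years:
        Calendar years of mortality follow-up, pooled downstream.
    census_window:
        A census form qualifies for follow-up year ``y`` when its year lies
        in ``(y - census_window, y]`` (rolling census design).
    weight_sd:
        Sigma of the lognormal survey weights before rescaling to mean 1.
    age_range:
        Closed age interval of the study population; ages above the upper
        bound are recorded at the bound (open-ended terminal age group).
    """

    n_individuals: int = 200_000
    seed: int = 0
    gompertz_a: dict = field(default_factory=lambda: {MALE: 3e-5, FEMALE: 1.5e-5})
    gompertz_b: dict = field(default_factory=lambda: {MALE: 0.10, FEMALE: 0.105})
    makeham_c: float = 0.0
    quintile_log_hr: tuple = tuple(float(np.log(h)) for h in DEFAULT_QUINTILE_HR)
    followup_years: tuple = (2016, 2017, 2018)
    census_window: int = 5
    weight_sd: float = 0.25
    age_range: tuple = (18, 100)

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if len(self.quintile_log_hr) != 5:
            raise ValueError("quintile_log_hr must have exactly 5 entries")
        if self.quintile_log_hr[0] != 0:
            raise ValueError("the reference quintile (q1) log hazard ratio must be 0")
        for sex in SEXES:
            if self.gompertz_b[sex] <= 0:
                raise ValueError("gompertz_b must be positive")
            if self.gompertz_a[sex] < 0:
                raise ValueError("gompertz_a must be nonnegative")
        if self.makeham_c < 0:
            raise ValueError("makeham_c must be nonnegative")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be nonnegative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min_age < max_age")
        if self.census_window < 1:
            raise ValueError("census_window must be >= 1")

    def hazard(self, age, sex, quintile):
        """True hazard ``mu(age, sex, q)``, constant within single years of age.

        ``age`` and ``quintile`` may be arrays (quintile in 1..5).
        """
        age = np.asarray(age, dtype=float)
        q = np.asarray(quintile)
        log_hr = np.asarray(self.quintile_log_hr)[q - 1]
        base = self.makeham_c + self.gompertz_a[sex] * np.exp(self.gompertz_b[sex] * age)
        return base * np.exp(log_hr)


def simulate_areas(n_areas: int, seed: int) -> pd.DataFrame:
    """Simulate an area table: deprivation scores and populations.

    Scores are standard normal (continuous, so ties have probability zero);
    populations are lognormal around ~2,000 inhabitants — heavy-tailed, like
    the sizes of small census geographies.

    Returns a DataFrame with columns ``area_id``, ``score``, ``population``.
    """
    if n_areas < 5:
        raise ValueError("need at least 5 areas to form 5 quintiles")
    rng = np.random.default_rng(seed)
    scores = rng.normal(0.0, 1.0, n_areas)
    population = rng.lognormal(mean=np.log(2000.0), sigma=1.0, size=n_areas)
    ids = [f"A{i:06d}" for i in range(n_areas)]
    return pd.DataFrame({"area_id": ids, "score": scores, "population": population})


def simulate_microdata(config: SimulationConfig, areas: pd.DataFrame) -> pd.DataFrame:
    """Simulate person-year records of the follow-up.

    Each individual receives a sex (fair coin), a residential area drawn
    proportional to area population (hence a deprivation score and a true
    quintile), one census form whose anteriority relative to each follow-up
    year is uniform over the census window, and a survey weight.  Ages
    advance by one year per follow-up year; death occurs with probability
    ``1 - exp(-mu)`` and removes the individual from later years.  A death
    still contributes its full weight to that year's population count.

    Returns a DataFrame with one row per person-year: ``person_id``, ``sex``,
    ``followup_year``, ``age``, ``census_year``, ``area_id``, ``area_score``,
    ``weight``, ``died``.  Deterministic given ``config.seed``.
    """
    from .cohort_prep import assign_quintiles

    if len(areas) == 0:
        raise ValueError("area table is empty")

    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    min_age, max_age = config.age_range

    sex = np.where(rng.random(n) < 0.5, MALE, FEMALE)
    p_area = areas["population"].to_numpy() / areas["population"].sum()
    area_idx = rng.choice(len(areas), size=n, p=p_area)
    # census-form anteriority: uniform lag in {0, ..., window-1} per person,
    # so census_year = followup_year - lag is uniform over the rolling window
    lag = rng.integers(0, config.census_window, size=n)
    age0 = rng.integers(min_age, max_age + 1, size=n)

    raw_w = rng.lognormal(mean=-0.5 * config.weight_sd**2, sigma=config.weight_sd, size=n)
    weight = raw_w.copy()
    for stratum in np.unique(lag):
        m = lag == stratum
        weight[m] = raw_w[m] / raw_w[m].mean()

    assignment = assign_quintiles(areas)
    area_q = (
        areas[["area_id"]]
        .merge(assignment, on="area_id")["quintile"]
        .to_numpy()
    )
    quintile = area_q[area_idx]
    area_ids = areas["area_id"].to_numpy()[area_idx]
    area_scores = areas["score"].to_numpy()[area_idx]

    mu_max = max(
        config.hazard(max_age, s, q) for s in SEXES for q in range(1, 6)
    )
    if mu_max > 1.0:
        warnings.warn(
            f"hazard exceeds 1/year at the terminal age (max {mu_max:.3g}); "
            "death probabilities are clipped at 1 - exp(-mu)",
            stacklevel=2,
        )

    person_id = np.arange(n)
    alive = np.ones(n, dtype=bool)
    frames = []
    for k, year in enumerate(config.followup_years):
        age = np.minimum(age0 + k, max_age)
        mu = np.empty(n)
        for s in SEXES:
            m = sex == s
            mu[m] = config.hazard(age[m], s, quintile[m])
        p_death = -np.expm1(-mu)
        dies = rng.random(n) < p_death
        rec = alive
        frames.append(
            pd.DataFrame(
                {
                    "person_id": person_id[rec],
                    "sex": sex[rec],
                    "followup_year": year,
                    "age": age[rec],
                    "census_year": year - lag[rec],
                    "area_id": area_ids[rec],
                    "area_score": area_scores[rec],
                    "weight": weight[rec],
                    "died": (dies[rec]).astype(int),
                }
            )
        )
        alive = alive & ~dies
    return pd.concat(frames, ignore_index=True)


def reference_from_truth(config: SimulationConfig, scale: str = "annual-probability") -> pd.DataFrame:
    """National reference mortality rates implied by the simulation truth.

    Averages the five quintile-specific mortality levels with equal (20%)
    population weights at every age and sex, standing in for a national
    life table against which the sample is calibrated.

    ``scale`` selects the quantity averaged:

    - ``"annual-probability"`` (default): the one-year death probability
      ``1 - exp(-mu_q)``.  This is the quantity the sample's
      deaths/population estimator targets (exposure counts a full year for
      deaths), so calibrating against it yields a coefficient ≈ 1 when
      sample and reference share the same truth.
    - ``"hazard"``: the hazard ``mu_q`` itself — the continuous-time force
      of mortality.

    Returns a DataFrame with columns ``age``, ``sex``, ``rate``.
    """
    if scale not in ("annual-probability", "hazard"):
        raise ValueError(f"unknown scale: {scale!r}")
    min_age, max_age = config.age_range
    ages = np.arange(min_age, max_age + 1)
    rows = []
    for sex in SEXES:
        levels = np.zeros(len(ages))
        for q in range(1, 6):
            mu = config.hazard(ages, sex, q)
            levels += 0.2 * (mu if scale == "hazard" else -np.expm1(-mu))
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "rate": levels}))
    return pd.concat(rows, ignore_index=True)


def true_life_expectancy(
    config: SimulationConfig, sex: str, quintile: int, age: int
) -> float:
    """Exact remaining life expectancy at ``age`` under the simulation truth.

    The generator's hazard is piecewise constant over single years of age,
    so the survival integral has a closed form: within a year with hazard
    ``mu`` the expected time lived is ``(1 - exp(-mu)) / mu`` given entry,
    and beyond the terminal age the hazard is frozen at its terminal value,
    giving an exponential tail with mean ``1/mu``.  Serves as the oracle
    for life-table accuracy checks.
    """
    min_age, max_age = config.age_range
    if not (min_age <= age <= max_age):
        raise ValueError(f"age {age} outside the simulated range {config.age_range}")
    ages = np.arange(age, max_age)
    mu = config.hazard(ages, sex, quintile)
    with np.errstate(invalid="ignore", divide="ignore"):
        lived = np.where(mu > 0, -np.expm1(-mu) / np.where(mu > 0, mu, 1.0), 1.0)
    surv = np.concatenate([[1.0], np.cumprod(np.exp(-mu))])
    e = float(np.sum(surv[:-1] * lived))
    mu_omega = float(config.hazard(max_age, sex, quintile))
    if mu_omega > 0:
        e += surv[-1] / mu_omega
    else:
        e = float("inf")
    return e
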