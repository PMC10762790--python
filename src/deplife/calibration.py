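"""Calibration of sample death counts to a national reference.

A survey sample can under- or over-estimate national mortality even after
design weighting.  The remedy used here is a scalar calibration
coefficient per sex: the ratio of the deaths a national reference table
would predict for the sample's exposure structure to the deaths the sample
actually observed,

    coefficient = sum_x e_x * rate_ref(x) / sum_x d_x ,

computed on the pooled (all-quintile) sample and then applied
multiplicatively to the death counts of every deprivation quintile before
smoothing.  Being a single factor per sex, calibration shifts every
quintile's rate curve by the same amount on the log scale and therefore
leaves all between-quintile rate ratios unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_prep import ALL


@dataclass
class CalibrationCoefficient:
    """Per-sex scalar rescaling sample deaths to the national level."""

    sex: str
    coefficient: float
    expected_deaths_national: float
    observed_deaths_sample: float


def compute_calibration(
    counts: pd.DataFrame, reference: pd.DataFrame, sex: str
) -> CalibrationCoefficient:
    """Calibration coefficient for one sex from the all-quintile counts.

    ``reference`` has columns ``age``, ``sex``, ``rate`` and must cover
    every age present in the counts.  Raises when the sample has no
    observed deaths (the ratio is undefined).
    """
    sample = counts[(counts["sex"] == sex) & (counts["quintile"] == ALL)]
    if len(sample) == 0:
        raise ValueError(f"counts contain no all-quintile margin for sex={sex!r}")
    ref = reference[reference["sex"] == sex][["age", "rate"]]
    merged = sample.merge(ref, on="age", how="left")
    if merged["rate"].isna().any():
        missing = merged.loc[merged["rate"].isna(), "age"].tolist()[:5]
        raise ValueError(f"reference table missing ages, e.g. {missing}")
    observed = float(merged["deaths"].sum())
    if observed <= 0:
        raise ValueError("no observed deaths in the sample; calibration undefined")
    expected = float((merged["exposure"] * merged["rate"]).sum())
    return CalibrationCoefficient(
        sex=sex,
        coefficient=expected / observed,
        expected_deaths_national=expected,
        observed_deaths_sample=observed,
    )


def apply_calibration(
    counts: pd.DataFrame, coeff: CalibrationCoefficient
) -> pd.DataFrame:
    """Rescale the death counts of one sex by its calibration coefficient.

    Deaths in every cell (all quintiles and the margin) of ``coeff.sex``
    are multiplied by the coefficient; exposures are untouched.  Returns a
    new counts table.
    """
    if coeff.coefficient <= 0:
        raise ValueError("calibration coefficient must be positive")
    out = counts.copy()
    mask = out["sex"] == coeff.sex
    out.loc[mask, "deaths"] = out.loc[mask, "deaths"] * coeff.coefficient
    return out


def calibrate_rates(
    rate_curve: pd.DataFrame, coeff: CalibrationCoefficient
) -> pd.DataFrame:
    """Rescale a smoothed rate curve (and its CI bounds) by the coefficient.

    This is how the pipeline applies calibration: scaling the fitted rates
    rather than the raw counts keeps the Poisson likelihood — and hence
    every CI width and every between-quintile rate ratio — exactly as the
    sample determined them, while shifting all levels to the national
    reference.  The log-scale standard error is untouched.
    """
    if coeff.coefficient <= 0:
        raise ValueError("calibration coefficient must be positive")
    out = rate_curve.copy()
    for col in ("rate", "ci_low", "ci_high"):
        out[col] = out[col] * coeff.coefficient
    return out
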