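"""Figures for the study outputs: rate curves, MRR curves, LE-gap bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort_prep import ALL, QUINTILES
from .synthetic_data import SEXES

_Q_COLORS = {1: "#2166ac", 2: "#67a9cf", 3: "#999999", 4: "#ef8a62", 5: "#b2182b"}


def plot_rate_curves(rates: pd.DataFrame):
    """Smoothed mortality rates by age and quintile, log scale, per sex."""
    fig, axes = plt.subplots(1, len(SEXES), figsize=(10, 4), sharey=True)
    for ax, sex in zip(axes, SEXES):
        sub = rates[rates["sex"] == sex]
        for q in QUINTILES:
            s = sub[sub["quintile"] == q]
            ax.plot(s["age"], s["rate"], color=_Q_COLORS[q], label=f"q{q}")
        s = sub[sub["quintile"] == ALL]
        if len(s):
            ax.plot(s["age"], s["rate"], "k--", lw=1, label="all")
        ax.set_yscale("log")
        ax.set_title(sex)
        ax.set_xlabel("age")
    axes[0].set_ylabel("mortality rate (per person-year)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_mrr_curves(mrr: pd.DataFrame):
    """MRR vs the least-deprived quintile by age, with 95% bands, per sex."""
    fig, axes = plt.subplots(1, len(SEXES), figsize=(10, 4), sharey=True)
    for ax, sex in zip(axes, SEXES):
        sub = mrr[mrr["sex"] == sex]
        for q in sorted(sub["quintile"].unique()):
            s = sub[sub["quintile"] == q]
            ax.plot(s["age"], s["mrr"], color=_Q_COLORS[q], label=f"q{q} vs q1")
            ax.fill_between(s["age"], s["ci_low"], s["ci_high"], color=_Q_COLORS[q], alpha=0.15)
        ax.axhline(1.0, color="k", lw=0.8)
        ax.set_title(sex)
        ax.set_xlabel("age")
    axes[0].set_ylabel("mortality rate ratio")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_le_gaps(le_gaps: pd.DataFrame):
    """Life-expectancy gap (q1 minus q) bars at the reporting ages, per sex."""
    ages = sorted(le_gaps["age"].unique())
    fig, axes = plt.subplots(len(ages), len(SEXES), figsize=(10, 3 * len(ages)), squeeze=False)
    for i, age in enumerate(ages):
        for j, sex in enumerate(SEXES):
            ax = axes[i][j]
            s = le_gaps[(le_gaps["sex"] == sex) & (le_gaps["age"] == age)]
            ax.bar([f"q{q}" for q in s["quintile"]], s["gap_years"],
                   color=[_Q_COLORS[q] for q in s["quintile"]])
            ax.set_title(f"{sex}, age {age}")
            ax.set_ylabel("LE gap vs q1 (years)")
    fig.tight_layout()
    return fig
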