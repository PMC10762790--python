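"""Period life tables from smoothed mortality rates.

The central rate m_x over a one-year age interval is converted to a
mortality quotient q_x (probability of dying within the interval given
survival to its start) under the piecewise-constant-hazard convention

    q_x = 1 - exp(-m_x),

which is exact when the hazard is flat within single years of age — the
same assumption the Poisson smoothing model makes.  The classical columns
follow with radix l_18 = 100,000:

    d_x = l_x q_x,   l_{x+1} = l_x - d_x,
    L_x = l_{x+1} + a_x d_x   (a_x = 0.5: deaths mid-interval on average),
    T_x = sum_{y >= x} L_y,   e_x = T_x / l_x.

The terminal age (100) is an open interval closed with the constant-hazard
rule L_omega = l_omega / m_omega, i.e. e_100 = 1/m_100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RADIX = 100_000.0

LIFE_TABLE_COLUMNS = ["age", "m_x", "q_x", "l_x", "d_x", "L_x", "T_x", "e_x"]


def rates_to_quotients(rates, convention: str = "exponential") -> np.ndarray:
    """Mortality quotients q_x from central rates m_x (terminal q = 1).

    ``rates`` is the ``m_x`` vector over the age grid, or a rate-curve
    DataFrame with a ``rate`` column.  ``convention`` is ``"exponential"``
    (q = 1 - exp(-m), exact under a flat within-interval hazard) or
    ``"actuarial"`` (q = m / (1 + 0.5 m), the mid-interval-exposure
    approximation).
    """
    if isinstance(rates, pd.DataFrame):
        m = rates["rate"].to_numpy(dtype=float)
    else:
        m = np.asarray(rates, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mortality rates must be positive")
    if convention == "exponential":
        q = -np.expm1(-m)
    elif convention == "actuarial":
        q = m / (1.0 + 0.5 * m)
    else:
        raise ValueError(f"unknown q-convention: {convention!r}")
    q = q.copy()
    q[-1] = 1.0  # open terminal interval: everyone alive at omega dies in it
    return q


def build_life_table(
    q_x: np.ndarray,
    m_x: np.ndarray,
    ages=None,
    radix: float = RADIX,
    a_x: float = 0.5,
) -> pd.DataFrame:
    """Complete period life table from quotients and central rates.

    ``q_x`` and ``m_x`` run over the same age grid (default 18..100) and
    the terminal quotient must be 1 so that the cohort is fully accounted
    for.  Returns a DataFrame with the eight classical columns.
    """
    q = np.asarray(q_x, dtype=float)
    m = np.asarray(m_x, dtype=float)
    if q.shape != m.shape:
        raise ValueError("q_x and m_x must have the same length")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quotients must lie in [0, 1]")
    if q[-1] != 1.0:
        raise ValueError("the terminal quotient must be 1 (open age interval)")
    n = len(q)
    if ages is None:
        ages = np.arange(18, 18 + n)
    ages = np.asarray(ages)

    l = np.empty(n)
    l[0] = radix
    for i in range(n - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q
    L = np.empty(n)
    L[:-1] = l[1:] + a_x * d[:-1]
    L[-1] = l[-1] / m[-1] if m[-1] > 0 else 0.0
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), np.nan)
    return pd.DataFrame(
        {"age": ages, "m_x": m, "q_x": q, "l_x": l, "d_x": d, "L_x": L, "T_x": T, "e_x": e}
    )


def life_table_from_rates(
    rate_curve: pd.DataFrame,
    convention: str = "exponential",
    radix: float = RADIX,
    a_x: float = 0.5,
) -> pd.DataFrame:
    """Life table straight from a smoothed rate curve (age, rate)."""
    c = rate_curve.sort_values("age")
    m = c["rate"].to_numpy(dtype=float)
    q = rates_to_quotients(m, convention=convention)
    return build_life_table(q, m, ages=c["age"].to_numpy(), radix=radix, a_x=a_x)


def life_expectancy_at(life_table: pd.DataFrame, age: int) -> float:
    """e_x read off a life table; raises when the age is off the grid."""
    row = life_table[life_table["age"] == age]
    if len(row) == 0:
        raise ValueError(f"age {age} not in the life table")
    return float(row["e_x"].iloc[0])


def life_expectancy_gap(lt_a: pd.DataFrame, lt_b: pd.DataFrame, age: int) -> float:
    """Gap e_x(a) - e_x(b) between two life tables at one age."""
    return life_expectancy_at(lt_a, age) - life_expectancy_at(lt_b, age)
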