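"""One-dimensional Poisson P-spline smoothing of mortality counts.

Death counts d_x at single years of age x are modelled as

    d_x ~ Poisson(e_x * mu_x),      log mu_x = B(x) a,

with e_x the person-years exposure entering as an offset and B a basis of
equally spaced cubic B-splines over the age range.  The P-spline approach
adds a difference penalty of order k on adjacent coefficients, so the
penalized log-likelihood is

    l(a) - lambda/2 * ||D_k a||^2 ,

maximised by penalized iteratively reweighted least squares (IRLS):

    (B' W B + lambda D'D) a = B' W z

with W = diag(fitted deaths) and z the working response.  The smoothing
parameter lambda is selected by minimising BIC = deviance + log(n) * ED,
where ED — the effective dimension — is the trace of the hat matrix.  With
a second-order penalty the lambda -> infinity limit is a log-linear
(Gompertz) hazard, and at any lambda the fit conserves the total death
count, because constants (and, for order 2, linear trends) lie in the
penalty's null space.

Coefficient uncertainty uses the penalized-information inverse
(B'WB + lambda D'D)^{-1}, giving pointwise confidence bands on the log
rate scale that downstream rate-ratio inference reuses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

#: Default smoothing-parameter grid: 10^-2 .. 10^7 at quarter-decade steps.
DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-2.0, 7.0 + 1e-9, 0.25))

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class SplineBasis:
    """Equally spaced B-spline basis and difference penalty on an age grid."""

    ages: np.ndarray
    n_segments: int
    degree: int
    penalty_order: int
    knots: np.ndarray
    B: np.ndarray
    D: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    def compatible_with(self, other: "SplineBasis") -> bool:
        return (
            self.degree == other.degree
            and self.n_segments == other.n_segments
            and np.array_equal(self.ages, other.ages)
            and np.allclose(self.knots, other.knots)
        )


def build_basis(
    age_min: int = 18,
    age_max: int = 100,
    n_segments: int = 21,
    degree: int = 3,
    penalty_order: int = 2,
) -> SplineBasis:
    """B-spline basis on the integer age grid with a difference penalty.

    Knots are equally spaced over ``[age_min, age_max]`` with ``n_segments``
    intervals, extended ``degree`` knots beyond each boundary (the standard
    P-spline construction), giving ``n_segments + degree`` basis functions.
    ``D`` is the ``penalty_order``-th order difference operator acting on
    the coefficient vector.
    """
    if age_max <= age_min:
        raise ValueError("age_max must exceed age_min")
    if n_segments < penalty_order + 1:
        raise ValueError("n_segments must be at least penalty_order + 1")
    ages = np.arange(age_min, age_max + 1)
    h = (age_max - age_min) / n_segments
    knots = age_min + h * np.arange(-degree, n_segments + degree + 1)
    B = BSpline.design_matrix(
        ages.astype(float), knots.astype(float), degree, extrapolate=False
    ).toarray()
    n_basis = n_segments + degree
    D = np.diff(np.eye(n_basis), n=penalty_order, axis=0)
    return SplineBasis(
        ages=ages,
        n_segments=n_segments,
        degree=degree,
        penalty_order=penalty_order,
        knots=knots,
        B=B,
        D=D,
    )


@dataclass
class PsplineFit:
    """A fitted penalized Poisson spline for one (sex, quintile) stratum."""

    coefficients: np.ndarray
    covariance: np.ndarray
    lam: float
    effective_dimension: float
    deviance: float
    bic: float
    converged: bool
    n_iter: int
    ages_used: np.ndarray
    fitted_deaths: np.ndarray
    degenerate: bool = False
    sex: str | None = None
    quintile: int | None = None


def _poisson_deviance(d: np.ndarray, dhat: np.ndarray) -> float:
    # zero-count cells contribute 2*dhat (the d*log(d/dhat) term vanishes)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(np.where(d > 0, d, 1.0) / dhat), 0.0)
    return float(2.0 * np.sum(term - (d - dhat)))


def fit_pspline(
    counts: pd.DataFrame,
    basis: SplineBasis,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> PsplineFit:
    """Fit the penalized Poisson spline to one stratum's counts.

    ``counts`` is a single-stratum slice with columns ``age``, ``deaths``,
    ``exposure`` on (a subset of) the basis's age grid.  Cells with zero
    exposure are excluded with a warning; zero-death cells stay in the
    likelihood.  Convergence is relative coefficient change below ``tol``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    c = counts.sort_values("age")
    ages = c["age"].to_numpy()
    pos = np.searchsorted(basis.ages, ages)
    if pos.max(initial=-1) >= len(basis.ages) or not np.array_equal(basis.ages[pos], ages):
        raise ValueError("counts contain ages outside the basis age grid")
    d = c["deaths"].to_numpy(dtype=float)
    e = c["exposure"].to_numpy(dtype=float)

    keep = e > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-exposure age cells from the fit",
            stacklevel=2,
        )
    d, e, pos = d[keep], e[keep], pos[keep]
    B = basis.B[pos]
    n_cells = len(d)
    meta = dict(lam=float(lam), ages_used=basis.ages[pos])

    if n_cells == 0 or d.sum() <= 0:
        # all-zero deaths: the MLE sits at the -inf log-rate boundary
        nb = basis.n_basis
        return PsplineFit(
            coefficients=np.full(nb, -np.inf),
            covariance=np.full((nb, nb), np.nan),
            effective_dimension=np.nan,
            deviance=0.0,
            bic=np.nan,
            converged=False,
            n_iter=0,
            fitted_deaths=np.zeros(n_cells),
            degenerate=True,
            **meta,
        )

    P = lam * (basis.D.T @ basis.D)
    # start from the crude log-rate, least-squares projected on the basis
    eta0 = np.log((d + 0.5) / e)
    a = np.linalg.lstsq(B, eta0, rcond=None)[0]

    converged = False
    n_iter = 0
    dev_prev = np.inf
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(B @ a, -60.0, 60.0)
        dhat = e * np.exp(eta)
        dhat = np.maximum(dhat, 1e-12)
        z = eta + (d - dhat) / dhat
        M = (B * dhat[:, None]).T @ B
        a_new = np.linalg.solve(M + P, B.T @ (dhat * z))
        delta = np.max(np.abs(a_new - a)) / max(np.max(np.abs(a_new)), 1e-12)
        a = a_new
        dev = _poisson_deviance(d, np.maximum(e * np.exp(np.clip(B @ a, -60.0, 60.0)), 1e-12))
        if delta < tol:
            converged = True
            break
        # boundary drift: with zero-death runs some coefficients head to
        # -inf while the fitted values (and deviance) have long converged
        if abs(dev - dev_prev) < 1e-10 * (abs(dev) + 0.1):
            converged = True
            break
        dev_prev = dev
    if not converged:
        warnings.warn(
            f"penalized IRLS did not converge in {max_iter} iterations (lambda={lam:g})",
            stacklevel=2,
        )

    eta = B @ a
    dhat = e * np.exp(eta)
    M = (B * dhat[:, None]).T @ B
    A = M + P
    cov = np.linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    ed = float(np.trace(np.linalg.solve(A, M)))
    dev = _poisson_deviance(d, dhat)
    bic = dev + np.log(n_cells) * ed
    return PsplineFit(
        coefficients=a,
        covariance=cov,
        effective_dimension=ed,
        deviance=dev,
        bic=bic,
        converged=converged,
        n_iter=n_iter,
        fitted_deaths=dhat,
        **meta,
    )


def select_lambda(
    counts: pd.DataFrame,
    basis: SplineBasis,
    grid=None,
) -> PsplineFit:
    """Fit over a lambda grid and return the minimum-BIC fit.

    Ties are broken toward the larger lambda (the smoother fit).  Raises if
    every grid point fails to converge.
    """
    if grid is None:
        grid = DEFAULT_LAMBDA_GRID
    grid = np.sort(np.asarray(list(grid), dtype=float))
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    best = None
    for lam in grid:
        fit = fit_pspline(counts, basis, lam)
        if fit.degenerate or not fit.converged:
            continue
        if best is None or fit.bic <= best.bic:
            best = fit
    if best is None:
        raise RuntimeError("no converged fit on the lambda grid")
    return best


def predict_rates(fit: PsplineFit, basis: SplineBasis) -> pd.DataFrame:
    """Predicted mortality rates with pointwise 95% CIs on the age grid.

    The linear predictor eta = B a is normal to first order with covariance
    B Cov B'; rates and bounds are exp-transformed, so bands are symmetric
    on the log scale and always positive.
    """
    if fit.degenerate:
        raise ValueError("cannot predict from a degenerate (all-zero-deaths) fit")
    if not fit.converged:
        warnings.warn("predicting from a non-converged fit", stacklevel=2)
    B = basis.B
    eta = B @ fit.coefficients
    var = np.einsum("ij,jk,ik->i", B, fit.covariance, B)
    se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {
            "age": basis.ages,
            "rate": np.exp(eta),
            "ci_low": np.exp(eta - Z_95 * se),
            "ci_high": np.exp(eta + Z_95 * se),
            "log_rate_se": se,
        }
    )
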