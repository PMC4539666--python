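"""Second-order fractional polynomial (FP2) dose-response models.

An FP2 model describes the mean log2 fold change at dose index ``i`` as

    mu(i) = beta0 + beta1 * f(i; p1) + beta2 * g(i; p1, p2)

with the two powers (p1, p2) drawn from the conventional grid
P = {-3, -2.5, ..., 1.5, 2}.  Power 0 denotes the natural logarithm and
a repeated power multiplies by an extra log factor, so the family stays
2-dimensional for every pair.  The pair minimising the AIC over the grid
is selected per gene; the intercept-only model serves as the no-dose-effect
null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .profiles import ExpressionProfile

#: Conventional fractional-polynomial power grid.
POWER_GRID: tuple[float, ...] = (-3, -2.5, -2, -1.5, -1, -0.5, 0, 0.5, 1, 1.5, 2)

#: All canonical (p1 <= p2) power pairs, repetition allowed: 66 candidates.
CANONICAL_PAIRS: tuple[tuple[float, float], ...] = tuple(
    combinations_with_replacement(POWER_GRID, 2)
)

#: Floor applied to the ML residual variance so the log-likelihood stays
#: finite on interpolating (RSS = 0) fits.
VARIANCE_FLOOR = 1e-12


def eval_f(i, p1: float):
    """First FP basis function: ``i**p1``, or ``log(i)`` when p1 == 0."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise ValueError("dose index must be >= 1")
    return np.log(i) if p1 == 0 else i**p1


def eval_g(i, p1: float, p2: float):
    """Second FP basis function.

    ``i**p2`` for a distinct nonzero second power; repeated powers gain a
    ``log(i)`` factor; a zero second power is ``log(i)`` (or ``log(i)**2``
    when both powers are zero).
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 1):
        raise ValueError("dose index must be >= 1")
    if p1 == p2 == 0:
        return np.log(i) ** 2
    if p2 == 0:
        return np.log(i)
    if p1 == p2:
        return np.log(i) * i**p2
    return i**p2


def fp_design_matrix(dose_idx, p1: float, p2: float) -> np.ndarray:
    """(N, 3) design [1, f(i; p1), g(i; p1, p2)] for per-observation doses."""
    dose_idx = np.asarray(dose_idx, dtype=float)
    return np.column_stack(
        [np.ones(dose_idx.size), eval_f(dose_idx, p1), eval_g(dose_idx, p1, p2)]
    )


@dataclass
class FPFit:
    """A maximum-likelihood Gaussian linear fit of an FP2 (or null) model.

    ``sigma2`` is the ML variance RSS/N (floored at ``VARIANCE_FLOOR``);
    ``aic = 2k - 2 logL`` with ``k`` counting mean parameters plus the
    variance.
    """

    powers: tuple[float, float] | None
    beta: np.ndarray
    sigma2: float
    logL: float
    aic: float
    n_obs: int
    rss: float
    rank: int
    cond: float
    variance_floored: bool = False

    @property
    def k_mean(self) -> int:
        return self.beta.size


def _gaussian_ml(rss: float, n: int) -> tuple[float, float, bool]:
    """ML variance, maximised log-likelihood, and whether the floor bit."""
    sigma2 = rss / n
    floored = sigma2 < VARIANCE_FLOOR
    if floored:
        sigma2 = VARIANCE_FLOOR
    logL = -0.5 * n * (np.log(2 * np.pi * sigma2) + rss / (n * sigma2))
    return sigma2, logL, floored


def fit_ols(y: np.ndarray, X: np.ndarray, powers=None) -> FPFit:
    """Minimum-norm least squares with Gaussian ML variance and AIC.

    Shared by the single-system, projected and interaction models; the
    caller supplies the design matrix.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    beta, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2, logL, floored = _gaussian_ml(rss, n)
    k = beta.size + 1  # mean parameters + variance
    cond = float(sv[0] / sv[-1]) if sv.size and sv[-1] > 0 else np.inf
    return FPFit(
        powers=powers,
        beta=beta,
        sigma2=sigma2,
        logL=float(logL),
        aic=float(2 * k - 2 * logL),
        n_obs=n,
        rss=rss,
        rank=int(rank),
        cond=cond,
        variance_floored=floored,
    )


def fit_fp(profile: ExpressionProfile, powers: tuple[float, float]) -> FPFit:
    """Fit the FP2 model with a fixed power pair to one profile."""
    if profile.n_obs < 4 or profile.n_dose_levels < 2:
        raise ValueError(
            "FP2 fit needs >= 4 observations over >= 2 distinct dose levels"
        )
    p1, p2 = powers
    X = fp_design_matrix(profile.dose_idx, p1, p2)
    return fit_ols(profile.values, X, powers=(float(p1), float(p2)))


def fit_null(profile: ExpressionProfile) -> FPFit:
    """Fit the intercept-only (no dose effect) model."""
    if profile.n_obs == 0:
        raise ValueError("empty profile")
    y = profile.values
    n = y.size
    beta = np.array([y.mean()])
    rss = float(((y - beta[0]) ** 2).sum())
    sigma2, logL, floored = _gaussian_ml(rss, n)
    return FPFit(
        powers=None,
        beta=beta,
        sigma2=sigma2,
        logL=float(logL),
        aic=float(2 * 2 - 2 * logL),
        n_obs=n,
        rss=rss,
        rank=1,
        cond=1.0,
        variance_floored=floored,
    )


def select_powers(profile: ExpressionProfile) -> FPFit:
    """AIC-best FP2 fit over all 66 canonical power pairs.

    Ties broken by the lexicographically smallest (p1, p2); since all FP2
    candidates share the same parameter count this is equivalent to
    minimising the residual sum of squares.
    """
    best: FPFit | None = None
    for powers in CANONICAL_PAIRS:
        fit = fit_fp(profile, powers)
        if best is None or fit.aic < best.aic - 1e-12:
            best = fit
    return best
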