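"""Negative-binomial probability model and mean-dispersion trend fits.

The package models the read count :math:`K` of a transcript in one sequencing
lane as

.. math:: K \\sim \\mathrm{NB}(\\mathrm{mean}=\\mu,\\ \\mathrm{var}=\\mu(1+\\phi\\mu)),

where :math:`\\phi \\ge 0` is the dispersion; :math:`\\phi = 0` recovers the
Poisson law.  Internally the usual (r, p) parameterisation is used with
``r = 1/phi`` and ``p = r/(r + mu)``.

This module provides the pmf, the law of sums of i.i.d. NB replicates,
per-transcript maximum-likelihood estimation, and the two mean-dispersion
trend fits used by the DE-test strategies: the hyperbolic form
``phi = a + b/mu`` (fitted with a gamma GLM) and the power law
``phi = c * mu**(alpha - 2)`` (fitted by log-log regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "NBParams",
    "ParametricDispersionFit",
    "PowerLawDispersionFit",
    "PHI_MIN",
    "PHI_MAX",
    "nb_pmf",
    "nb_logpmf",
    "pooled_sum_params",
    "estimate_nb_mle",
    "fit_parametric_dispersion",
    "fit_powerlaw_dispersion",
]

#: Bounds for dispersion estimation.  The lower bound stands in for "Poisson"
#: (variance equal to the mean); the upper bound is far above any dispersion
#: seen in bulk RNA-Seq.
PHI_MIN = 1e-8
PHI_MAX = 50.0


@dataclass(frozen=True)
class NBParams:
    """NB(mean, dispersion) parameter pair for one transcript in one lane.

    ``mean == 0`` is a degenerate sentinel produced by estimating from an
    all-zero count vector; such transcripts carry no information and are
    excluded from simulation.
    """

    mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or self.mean < 0:
            raise ValueError(f"mean must be finite and >= 0, got {self.mean}")
        if not np.isfinite(self.dispersion) or self.dispersion < 0:
            raise ValueError(
                f"dispersion must be finite and >= 0, got {self.dispersion}"
            )

    @property
    def variance(self) -> float:
        return self.mean * (1.0 + self.dispersion * self.mean)

    @property
    def is_degenerate(self) -> bool:
        return self.mean == 0.0


@dataclass(frozen=True)
class ParametricDispersionFit:
    """Hyperbolic mean-dispersion trend ``phi(mu) = a + b/mu`` (a, b >= 0)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be non-negative")

    def predict(self, mean):
        mean = np.asarray(mean, dtype=float)
        return self.a + self.b / mean


@dataclass(frozen=True)
class PowerLawDispersionFit:
    """Power-law mean-dispersion trend ``phi(mu) = c * mu**(alpha - 2)``.

    ``alpha = 2`` is the constant-dispersion (NB2) case and ``alpha = 1``
    the NB1 case (variance proportional to the mean).
    """

    c: float
    alpha: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")

    def predict(self, mean):
        mean = np.asarray(mean, dtype=float)
        return self.c * mean ** (self.alpha - 2.0)


def nb_logpmf(k, mean, dispersion):
    """Log pmf of NB(mean, var = mean(1+phi*mean)), vectorised.

    Falls back to the Poisson log pmf in the small-dispersion limit
    (``phi < 1e-12``) where the NB formula loses precision.
    """
    k = np.asarray(k, dtype=float)
    mean = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("k must contain non-negative integers")
    if np.any(mean <= 0):
        raise ValueError("mean must be positive")
    if np.any(phi < 0):
        raise ValueError("dispersion must be non-negative")

    k, mean, phi = np.broadcast_arrays(k, mean, phi)
    out = np.empty(k.shape, dtype=float)
    poiss = phi < 1e-12
    if np.any(poiss):
        m = mean[poiss]
        out[poiss] = k[poiss] * np.log(m) - m - gammaln(k[poiss] + 1.0)
    nb = ~poiss
    if np.any(nb):
        r = 1.0 / phi[nb]
        m = mean[nb]
        kk = k[nb]
        out[nb] = (
            gammaln(kk + r)
            - gammaln(r)
            - gammaln(kk + 1.0)
            - r * np.log1p(m / r)
            + kk * (np.log(m) - np.log(r + m))
        )
    return out if out.ndim else float(out)


def nb_pmf(k, params: NBParams):
    """P(K = k) under ``params``; ``k`` may be a scalar or array of ints."""
    if params.is_degenerate:
        raise ValueError("cannot evaluate pmf of a degenerate (mean 0) transcript")
    return np.exp(nb_logpmf(k, params.mean, params.dispersion))


def pooled_sum_params(params: NBParams, n_reps: int) -> NBParams:
    """Distribution of the sum of ``n_reps`` i.i.d. NB(mu, phi) draws.

    The sum of n i.i.d. NB variables with common success probability is NB
    with the shape parameters added, which in the (mean, dispersion)
    parameterisation is ``NB(n*mu, phi/n)``.  This is the per-condition
    pooled-count law used by the exact conditional test.
    """
    if int(n_reps) != n_reps or n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    return NBParams(mean=params.mean * n_reps, dispersion=params.dispersion / n_reps)


def _profile_loglik(phi: float, counts: np.ndarray, mean: float) -> float:
    return float(np.sum(nb_logpmf(counts, mean, phi)))


def estimate_nb_mle(
    counts, phi_min: float = PHI_MIN, phi_max: float = PHI_MAX
) -> NBParams:
    """Per-transcript MLE of (mu, phi) from replicate counts.

    The MLE of the mean is the sample mean for any fixed dispersion, so the
    dispersion is found by bounded maximisation of the profile
    log-likelihood over ``[phi_min, phi_max]``.  When the sample variance
    does not exceed the sample mean the profile is maximised at the boundary
    and the dispersion clamps to ``phi_min``.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("counts must be a 1-D vector of length >= 2")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    counts = counts.astype(float)
    mean = float(counts.mean())
    if mean == 0.0:
        return NBParams(mean=0.0, dispersion=phi_min)  # degenerate sentinel
    if counts.var(ddof=1) <= mean:
        return NBParams(mean=mean, dispersion=phi_min)
    res = optimize.minimize_scalar(
        lambda lp: -_profile_loglik(np.exp(lp), counts, mean),
        bounds=(np.log(phi_min), np.log(phi_max)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return NBParams(mean=mean, dispersion=float(np.exp(res.x)))


def fit_parametric_dispersion(means, dispersions) -> ParametricDispersionFit:
    """Fit ``phi = a + b/mu`` to per-transcript dispersion estimates.

    Uses a gamma-family GLM with identity link on the covariate 1/mu,
    initialised from (and falling back to) ordinary least squares.  Because
    per-transcript dispersion estimates at small replication are extremely
    noisy (including values clamped near zero and occasional huge
    outliers), the GLM is iterated with outlier exclusion: points whose
    ratio to the current curve falls outside ``(1e-4, 15)`` are dropped and
    the curve refitted until the coefficients stabilise.  The coefficients
    are clamped at zero.
    """
    means = np.asarray(means, dtype=float)
    phis = np.asarray(dispersions, dtype=float)
    if means.shape != phis.shape or means.ndim != 1:
        raise ValueError("means and dispersions must be 1-D vectors of equal length")
    ok = np.isfinite(means) & np.isfinite(phis) & (means > 0) & (phis > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 usable (mean, dispersion) points")
    x = 1.0 / means[ok]
    y = phis[ok]
    exog = np.column_stack([np.ones_like(x), x])
    ols = np.linalg.lstsq(exog, y, rcond=None)[0]
    coefs = np.clip(ols, 1e-12, None)
    try:
        import warnings

        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(12):
                pred = coefs[0] + coefs[1] * x
                ratio = y / np.clip(pred, 1e-300, None)
                good = (ratio > 1e-4) & (ratio < 15.0)
                if good.sum() < 3:
                    break
                glm = sm.GLM(
                    y[good],
                    exog[good],
                    family=sm.families.Gamma(link=sm.families.links.Identity()),
                )
                fit = glm.fit(start_params=coefs, maxiter=200)
                new = np.asarray(fit.params)
                if not np.all(np.isfinite(new)) or np.any(new < -1e-6):
                    break
                done = np.all(np.abs(new - coefs) <= 1e-6 * (np.abs(coefs) + 1e-12))
                coefs = np.clip(new, 1e-12, None)
                if done:
                    break
    except Exception:
        coefs = ols  # keep OLS estimates
    a, b = np.clip(coefs, 0.0, None)
    return ParametricDispersionFit(a=float(a), b=float(b))


def fit_powerlaw_dispersion(means, dispersions) -> PowerLawDispersionFit:
    """Fit ``phi = c * mu**(alpha-2)`` by regressing log(phi) on log(mu).

    Pairs with non-positive dispersion (or mean) are excluded before the
    regression; the slope estimates ``alpha - 2`` and the intercept
    ``log(c)``.
    """
    means = np.asarray(means, dtype=float)
    phis = np.asarray(dispersions, dtype=float)
    if means.shape != phis.shape or means.ndim != 1:
        raise ValueError("means and dispersions must be 1-D vectors of equal length")
    ok = np.isfinite(means) & np.isfinite(phis) & (means > 0) & (phis > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 positive (mean, dispersion) pairs")
    lx = np.log(means[ok])
    ly = np.log(phis[ok])
    if np.allclose(lx, lx[0]):
        raise ValueError("means are constant; power-law slope is unidentifiable")
    reg = stats.linregress(lx, ly)
    return PowerLawDispersionFit(c=float(np.exp(reg.intercept)), alpha=float(reg.slope + 2.0))
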