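"""Uncertainty quantification for fitted Emax risk models.

Variance-covariance matrices come from a central finite-difference Hessian of
the negative log-likelihood at the optimum, evaluated on the unconstrained
internal scale and mapped to the natural parameter scale with the delta
method.  Concentration-risk confidence bands come from parametric Monte-Carlo
forward propagation: parameter vectors are drawn from a multivariate normal
on the internal scale (so every draw is an admissible parameter set), pushed
through the model on a concentration grid, and summarised pointwise by the
median and equal-tailed quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .model import EmaxRiskResults, NonIdentifiableError, natural_from_internal
from .params import PARAM_NAMES, ParameterError

__all__ = [
    "RiskCurve",
    "finite_difference_hessian",
    "hessian_vcov",
    "parameter_ci",
    "propagate_curve",
    "default_grid",
]


def default_grid(lo: float = 10.0, hi: float = 100_000.0, n: int = 200) -> np.ndarray:
    """Log-spaced NT-proBNP grid (pg/mL) covering the clinically relevant range."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class RiskCurve:
    """Concentration grid with the propagated median risk and CI band."""

    grid: np.ndarray
    median_prob: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    n_samples: int

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ParameterError("grid must be strictly increasing")
        if not (0.0 < self.level < 1.0):
            raise ParameterError("level must lie in (0, 1)")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        for name, arr in (("median_prob", self.median_prob),
                          ("lo", self.lo), ("hi", self.hi)):
            a = np.asarray(arr, dtype=float)
            if a.shape != g.shape:
                raise ParameterError(f"{name} must match the grid in length")
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if np.any(self.lo > self.median_prob + 1e-12) or np.any(
                self.median_prob > self.hi + 1e-12):
            raise ParameterError("band must satisfy lo <= median <= hi pointwise")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ntprobnp_pgml": self.grid,
            "median_prob": self.median_prob,
            "lo": self.lo,
            "hi": self.hi,
        })


def finite_difference_hessian(func, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of ``func`` at ``theta``.

    Per-coordinate step ``rel_step * (1 + |theta_i|)``; off-diagonal entries
    are symmetric by construction (four-point cross formula).
    """

    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((k, k), dtype=float)
    f0 = func(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (func(theta + ei) - 2.0 * f0 + func(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp = func(theta + ei + ej)
            fmm = func(theta - ei - ej)
            fpm = func(theta + ei - ej)
            fmp = func(theta - ei + ej)
            H[i, j] = H[j, i] = (fpp + fmm - fpm - fmp) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _invert_hessian(H: np.ndarray, free_names) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(H)
    if np.any(eigval <= 0):
        worst = int(np.argmin(eigval))
        direction = eigvec[:, worst]
        offender = free_names[int(np.argmax(np.abs(direction)))]
        raise NonIdentifiableError(
            f"likelihood Hessian is not positive definite; the flat direction "
            f"is dominated by parameter '{offender}' (non-identified). "
            f"Consider refitting with '{offender}' fixed."
        )
    cov = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    return 0.5 * (cov + cov.T)


def _internal_vcov(fit: EmaxRiskResults, rel_step: float = 1e-4) -> np.ndarray:
    """Inverse finite-difference Hessian on the internal scale."""
    if rel_step <= 0:
        raise ParameterError("finite-difference step must be > 0")
    nll = fit.model._objective(fit.mask)
    H = finite_difference_hessian(nll, fit.theta, rel_step=rel_step)
    return _invert_hessian(H, fit.free_names)


def _natural_jacobian(fit: EmaxRiskResults, rel_step: float = 1e-6) -> np.ndarray:
    """d(natural free params)/d(internal coords) by central differences."""
    theta = fit.theta
    free_idx = [PARAM_NAMES.index(n) for n in fit.free_names]
    k = theta.size
    J = np.empty((len(free_idx), k), dtype=float)
    for j in range(k):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        np_ = natural_from_internal(tp, fit.mask)[free_idx]
        nm = natural_from_internal(tm, fit.mask)[free_idx]
        J[:, j] = (np_ - nm) / (2.0 * h)
    return J


def hessian_vcov(rows, fit: EmaxRiskResults, rel_step: float = 1e-4) -> np.ndarray:
    """Natural-scale variance-covariance of the free parameters.

    Computes the inverse finite-difference Hessian of the negative
    log-likelihood at the optimum (internal scale) and back-transforms with
    the delta method.  ``rows`` must be the data the fit was computed on;
    they are accepted explicitly so the function can also be used on an
    externally reconstructed fit.

    Raises
    ------
    NonIdentifiableError
        If the Hessian is not positive definite; the message names the
        parameter dominating the flat direction and advises a
        fixed-parameter refit.
    """

    from .model import EmaxRiskModel, _as_xy

    if not fit.converged:
        raise ParameterError("variance estimation requires a converged fit")
    x, y = _as_xy(rows)
    if not (np.array_equal(x, fit.model.exog) and np.array_equal(y, fit.model.endog)):
        fit = _rebind(fit, EmaxRiskModel(y, x))
    cov_int = _internal_vcov(fit, rel_step=rel_step)
    J = _natural_jacobian(fit)
    cov_nat = J @ cov_int @ J.T
    return 0.5 * (cov_nat + cov_nat.T)


def _rebind(fit: EmaxRiskResults, model) -> EmaxRiskResults:
    return EmaxRiskResults(
        model=model, params=fit.params, mask=fit.mask, theta=fit.theta,
        nll=fit.nll, converged=fit.converged, identified=fit.identified,
        options=fit.options,
    )


def parameter_ci(fit: EmaxRiskResults, vcov: np.ndarray | None = None,
                 level: float = 0.90) -> pd.DataFrame:
    """Per-parameter estimate, standard error and normal-approximation CI.

    Fixed parameters are reported with ``se = 0`` and ``lo = hi = value``,
    flagged in the ``fixed`` column.
    """

    if not (0.0 < level < 1.0):
        raise ParameterError("level must lie in (0, 1)")
    cov = fit.cov_params() if vcov is None else np.asarray(vcov, dtype=float)
    diag = np.diag(cov)
    if np.any(diag < 0):
        raise NonIdentifiableError("variance-covariance has negative diagonal entries")
    z = norm.ppf(0.5 + level / 2.0)
    est = fit.params.as_array()
    se = np.zeros(4)
    free_idx = [PARAM_NAMES.index(n) for n in fit.free_names]
    se[free_idx] = np.sqrt(diag)
    lo = est - z * se
    hi = est + z * se
    fixed = [fit.mask.is_fixed(n) for n in PARAM_NAMES]
    return pd.DataFrame(
        {"estimate": est, "se": se, "lo": lo, "hi": hi, "fixed": fixed},
        index=list(PARAM_NAMES),
    )


def propagate_curve(fit: EmaxRiskResults, vcov_internal: np.ndarray, grid,
                    n_samples: int = 10_000, level: float = 0.90,
                    seed: int = 0) -> RiskCurve:
    """Monte-Carlo forward propagation of parameter uncertainty to the curve.

    Draws ``n_samples`` parameter vectors from a multivariate normal centred
    at the internal-scale estimates with covariance ``vcov_internal``, maps
    each through the constraint-preserving transform and the Emax function at
    every grid point, and reports the pointwise median and equal-tailed
    interval at ``level``.  Deterministic for a fixed ``seed``.
    """

    if n_samples < 100:
        raise ParameterError("n_samples must be >= 100 for a stable band")
    if not (0.0 < level < 1.0):
        raise ParameterError("level must lie in (0, 1)")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ParameterError("grid must be a non-empty 1-D array")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing")
    if np.any(grid < 0):
        raise ParameterError("grid concentrations must be >= 0")
    cov = np.asarray(vcov_internal, dtype=float)
    k = fit.theta.size
    if cov.shape != (k, k):
        raise ParameterError("vcov dimension must match the number of free parameters")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ParameterError("vcov must be symmetric")

    rng = np.random.default_rng(seed)
    if np.allclose(cov, 0.0):
        draws = np.tile(fit.theta, (n_samples, 1))
    else:
        draws = rng.multivariate_normal(fit.theta, cov, size=n_samples,
                                        method="svd")
    nat = np.atleast_2d(natural_from_internal(draws, fit.mask))
    p0, pmax, ec50, gamma = nat[:, 0], nat[:, 1], nat[:, 2], nat[:, 3]

    with np.errstate(divide="ignore"):
        ln_grid = np.where(grid > 0, np.log(grid), -np.inf)
    # (n_samples, n_grid) probabilities; x = 0 contributes the baseline only.
    z = gamma[:, None] * (ln_grid[None, :] - np.log(ec50)[:, None])
    probs = p0[:, None] + pmax[:, None] * np.where(
        np.isneginf(ln_grid)[None, :], 0.0, expit(z))

    alpha = 1.0 - level
    lo, med, hi = np.quantile(probs, [alpha / 2.0, 0.5, 1.0 - alpha / 2.0], axis=0)
    return RiskCurve(grid=grid, median_prob=med, lo=lo, hi=hi,
                     level=level, n_samples=n_samples)
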