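"""Maximum-likelihood fitting of the Emax risk function to binary endpoints.

The public surface follows the Model/Results idiom: :class:`EmaxRiskModel`
wraps one cohort's (concentration, event) data, its :meth:`~EmaxRiskModel.fit`
returns an :class:`EmaxRiskResults` carrying the estimates, their
variance-covariance matrix, and reporting/propagation methods.

Parameters may be selectively fixed through a :class:`FixedMask`, mirroring
the two published regimes: gamma pinned at 1 (keeping the model a plain
rectangular hyperbola in concentration), or the log-logistic regime with
``p0 = 0`` and ``pmax = 1`` where only ``ec50`` and ``gamma`` are estimated.

Optimization runs on an unconstrained internal scale::

    p0   = expit(t0) * (1 - pmax_fixed)   (headroom-aware logit)
    pmax = expit(t1) * (1 - p0)
    ec50 = exp(t2)
    gamma = exp(t3)

so every visited point satisfies 0 <= p0 <= p0 + pmax <= 1, ec50 > 0,
gamma > 0, for any combination of fixed parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .params import PARAM_NAMES, EmaxParams, ParameterError, emax_probability

__all__ = [
    "FixedMask",
    "FitOptions",
    "EmaxRiskModel",
    "EmaxRiskResults",
    "NonIdentifiableError",
    "negative_log_likelihood",
    "fit_emax",
]

_LOGIT_BOUNDARY = 15.0  # |logit| beyond this is treated as a boundary estimate


class NonIdentifiableError(RuntimeError):
    """Raised when the data cannot identify the requested free parameters."""


@dataclass(frozen=True)
class FixedMask:
    """Which parameters are held fixed during optimization, and at what value.

    ``None`` marks a parameter as free.  At least one parameter must remain
    free, and the fixed values must themselves be admissible.
    """

    p0: Optional[float] = None
    pmax: Optional[float] = None
    ec50: Optional[float] = None
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if all(v is not None for v in self.as_tuple()):
            raise ParameterError("at least one parameter must be free")
        for name, value, lo, hi in (
            ("p0", self.p0, 0.0, 1.0),
            ("pmax", self.pmax, 0.0, 1.0),
        ):
            if value is not None and not (lo <= value <= hi):
                raise ParameterError(f"fixed {name}={value} outside [{lo}, {hi}]")
        for name, value in (("ec50", self.ec50), ("gamma", self.gamma)):
            if value is not None and not value > 0:
                raise ParameterError(f"fixed {name}={value} must be > 0")
        if self.p0 is not None and self.pmax is not None and self.p0 + self.pmax > 1 + 1e-12:
            raise ParameterError("fixed p0 + pmax exceeds 1")
        # A parameter pinned to the full probability range leaves no headroom
        # for the other; require the companion to be fixed too.
        if self.pmax is not None and self.pmax >= 1.0 and self.p0 is None:
            raise ParameterError("pmax fixed at 1 requires p0 to be fixed (at 0)")
        if self.p0 is not None and self.p0 >= 1.0 and self.pmax is None:
            raise ParameterError("p0 fixed at 1 requires pmax to be fixed (at 0)")

    def as_tuple(self):
        return (self.p0, self.pmax, self.ec50, self.gamma)

    @property
    def free_names(self) -> tuple:
        return tuple(n for n, v in zip(PARAM_NAMES, self.as_tuple()) if v is None)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def is_fixed(self, name: str) -> bool:
        return getattr(self, name) is not None

    @classmethod
    def gamma_fixed(cls, gamma: float = 1.0) -> "FixedMask":
        """Hyperbolic regime: p0, pmax, ec50 free; shape exponent pinned."""
        return cls(gamma=gamma)

    @classmethod
    def log_logistic(cls) -> "FixedMask":
        """Log-logistic regime: p0 = 0 and pmax = 1 fixed; ec50, gamma free."""
        return cls(p0=0.0, pmax=1.0)

    @classmethod
    def free(cls) -> "FixedMask":
        return cls()


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    n_starts perturbed restarts (seeded) guard against local minima on
    likelihood surfaces that are nearly flat in ``pmax`` when few
    high-concentration observations are available.
    """

    maxiter: int = 500
    tol: float = 1e-8
    n_starts: int = 5
    seed: int = 0
    start_scale: float = 0.5
    fd_rel_step: float = 1e-4


# ---------------------------------------------------------------------------
# internal <-> natural scale


def natural_from_internal(theta: np.ndarray, mask: FixedMask) -> np.ndarray:
    """Map internal free-parameter coordinates to the natural (p0, pmax, ec50,
    gamma) scale.  ``theta`` may be a vector (n_free,) or a matrix
    (n_samples, n_free); the result has one natural row per input row."""

    theta_in = np.asarray(theta, dtype=float)
    one_dimensional = theta_in.ndim <= 1
    theta = np.atleast_2d(theta_in)
    n = theta.shape[0]
    out = np.empty((n, 4), dtype=float)
    j = 0
    if mask.p0 is None:
        cap0 = 1.0 - (mask.pmax if mask.pmax is not None else 0.0)
        out[:, 0] = expit(theta[:, j]) * cap0
        j += 1
    else:
        out[:, 0] = mask.p0
    if mask.pmax is None:
        out[:, 1] = expit(theta[:, j]) * (1.0 - out[:, 0])
        j += 1
    else:
        out[:, 1] = mask.pmax
    if mask.ec50 is None:
        out[:, 2] = np.exp(theta[:, j])
        j += 1
    else:
        out[:, 2] = mask.ec50
    if mask.gamma is None:
        out[:, 3] = np.exp(theta[:, j])
        j += 1
    else:
        out[:, 3] = mask.gamma
    return out[0] if one_dimensional else out


def internal_from_natural(params: EmaxParams, mask: FixedMask) -> np.ndarray:
    """Inverse of :func:`natural_from_internal` for a single parameter set."""

    eps = 1e-9
    theta = []
    if mask.p0 is None:
        cap0 = 1.0 - (mask.pmax if mask.pmax is not None else 0.0)
        theta.append(logit(np.clip(params.p0 / cap0, eps, 1 - eps)))
    if mask.pmax is None:
        cap1 = 1.0 - params.p0
        theta.append(logit(np.clip(params.pmax / max(cap1, eps), eps, 1 - eps)))
    if mask.ec50 is None:
        theta.append(np.log(params.ec50))
    if mask.gamma is None:
        theta.append(np.log(params.gamma))
    return np.asarray(theta, dtype=float)


# ---------------------------------------------------------------------------
# likelihood


def _as_xy(rows) -> tuple:
    """Accept a sequence of AnalysisRow-like objects, a DataFrame, or a pair
    of arrays, returning (concentrations, events) float/int arrays."""

    if isinstance(rows, tuple) and len(rows) == 2:
        x, y = rows
    elif isinstance(rows, pd.DataFrame):
        x, y = rows["ntprobnp_pgml"].to_numpy(), rows["event"].to_numpy()
    else:
        rows = list(rows)
        if len(rows) == 0:
            raise ParameterError("no observations supplied")
        x = np.array([r.nt_probnp for r in rows], dtype=float)
        y = np.array([r.event for r in rows], dtype=int)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size == 0:
        raise ParameterError("no observations supplied")
    if x.shape != y.shape:
        raise ParameterError("concentration and event vectors differ in length")
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ParameterError("concentrations must be finite and >= 0")
    if not np.all(np.isin(y, (0, 1))):
        raise ParameterError("events must be binary (0/1)")
    return x, y.astype(int)


def negative_log_likelihood(rows, params: EmaxParams) -> float:
    """Bernoulli negative log-likelihood of the endpoint data under ``params``.

    Returns ``inf`` (rather than raising) when a predicted probability of
    exactly 0 or 1 contradicts an observed outcome, steering optimizers away
    from such configurations.
    """

    x, y = _as_xy(rows)
    p = np.atleast_1d(emax_probability(x, params))
    conflict = ((y == 1) & (p <= 0.0)) | ((y == 0) & (p >= 1.0))
    if np.any(conflict):
        return float("inf")
    with np.errstate(divide="ignore"):
        ll = np.where(y == 1, np.log(p), np.log1p(-p))
    return float(-np.sum(ll))


# ---------------------------------------------------------------------------
# model / results


class EmaxRiskModel:
    """Emax risk model for one cohort.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Binary composite endpoint per patient (death or transplant within
        the cohort's horizon).
    exog : array-like of float
        Per-patient NT-proBNP summary concentration, pg/mL.
    """

    def __init__(self, endog, exog):
        self.exog, self.endog = _as_xy((exog, endog))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, conc_col: str = "ntprobnp_pgml",
                       event_col: str = "event") -> "EmaxRiskModel":
        return cls(data[event_col].to_numpy(), data[conc_col].to_numpy())

    @classmethod
    def from_rows(cls, rows: Sequence) -> "EmaxRiskModel":
        x, y = _as_xy(rows)
        return cls(y, x)

    @property
    def nobs(self) -> int:
        return int(self.exog.size)

    @property
    def n_events(self) -> int:
        return int(self.endog.sum())

    def loglike(self, params: EmaxParams) -> float:
        return -negative_log_likelihood((self.exog, self.endog), params)

    def _objective(self, mask: FixedMask):
        x, y = self.exog, self.endog
        ln_x = np.full_like(x, -np.inf)
        pos = x > 0
        ln_x[pos] = np.log(x[pos])

        def nll(theta: np.ndarray) -> float:
            nat = np.atleast_2d(natural_from_internal(theta, mask))[0]
            p0, pmax, ec50, gamma = nat
            ratio = np.where(pos, expit(gamma * (ln_x - np.log(ec50))), 0.0)
            p = p0 + pmax * ratio
            conflict = ((y == 1) & (p <= 0.0)) | ((y == 0) & (p >= 1.0))
            if np.any(conflict):
                return float("inf")
            with np.errstate(divide="ignore"):
                ll = np.where(y == 1, np.log(p), np.log1p(-p))
            return float(-ll.sum())

        return nll

    def _default_start(self, mask: FixedMask) -> EmaxParams:
        rate = float(np.clip(self.endog.mean(), 1e-3, 1 - 1e-3))
        p0 = mask.p0 if mask.p0 is not None else rate / 2.0
        cap = 1.0 - p0
        pmax = mask.pmax if mask.pmax is not None else min(rate, 0.99 * cap)
        pmax = max(pmax, 1e-3) if mask.pmax is None else pmax
        ec50 = mask.ec50 if mask.ec50 is not None else float(np.median(self.exog[self.exog > 0]))
        gamma = mask.gamma if mask.gamma is not None else 1.0
        return EmaxParams(p0=p0, pmax=pmax, ec50=ec50, gamma=gamma)

    def fit(self, mask: Optional[FixedMask] = None,
            options: Optional[FitOptions] = None) -> "EmaxRiskResults":
        """Maximize the Bernoulli likelihood over the free parameters.

        Raises
        ------
        NonIdentifiableError
            If the cohort contains no events or no non-events (the event
            probability scale is then unconstrained).
        """

        mask = mask if mask is not None else FixedMask.free()
        options = options if options is not None else FitOptions()
        if self.n_events == 0 or self.n_events == self.nobs:
            raise NonIdentifiableError(
                "data contain only events or only non-events; "
                "the event-probability parameters are not identifiable"
            )

        nll = self._objective(mask)
        theta0 = internal_from_natural(self._default_start(mask), mask)
        rng = np.random.default_rng(options.seed)
        starts = [theta0] + [
            theta0 + rng.normal(0.0, options.start_scale, size=theta0.size)
            for _ in range(max(options.n_starts - 1, 0))
        ]

        candidates = []
        for start in starts:
            res = minimize(
                nll, start, method="BFGS",
                options={"gtol": options.tol, "maxiter": options.maxiter},
            )
            if np.isfinite(res.fun):
                candidates.append(res)
        if not candidates:
            raise NonIdentifiableError("no optimizer start produced a finite likelihood")

        best_nll = min(c.fun for c in candidates)
        # Ties (within tolerance) broken by lowest ec50 for determinism.
        tied = [c for c in candidates if c.fun <= best_nll + max(options.tol, 1e-10)]

        def _ec50_of(c):
            return np.atleast_2d(natural_from_internal(c.x, mask))[0][2]

        best = min(tied, key=_ec50_of)
        # Derivative-free polish: refines the quasi-Newton solution and gives a
        # convergence verdict on the nll-change scale, which is robust to the
        # numeric-gradient noise that dominates |grad| at large n.
        fatol = options.tol * max(1.0, abs(best.fun))
        polish = minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": fatol, "maxiter": 400 * best.x.size},
        )
        # keep the quasi-Newton point (gradient-centred) unless the polish
        # achieves a real improvement beyond the nll tolerance
        improved = polish.fun < best.fun - fatol
        theta_hat = polish.x if improved else best.x
        best_fun = polish.fun if improved else best.fun
        nat = np.atleast_2d(natural_from_internal(theta_hat, mask))[0]
        estimates = EmaxParams.from_array(nat)
        converged = bool(best.success or polish.success)

        identified = self._check_identified(theta_hat, mask)

        result = EmaxRiskResults(
            model=self,
            params=estimates,
            mask=mask,
            theta=theta_hat,
            nll=float(best_fun),
            converged=converged,
            identified=identified,
            options=options,
        )
        return result

    def _check_identified(self, theta: np.ndarray, mask: FixedMask) -> bool:
        """Boundary estimates on the internal scale signal non-identifiability
        (e.g. pmax drifting to 1 when high-concentration data are sparse)."""
        j = 0
        ok = True
        for name in PARAM_NAMES:
            if mask.is_fixed(name):
                continue
            t = theta[j]
            if name in ("p0", "pmax") and abs(t) > _LOGIT_BOUNDARY:
                ok = False
            if name == "ec50":
                x = self.exog[self.exog > 0]
                if x.size and not (np.log(x.min()) - 7 < t < np.log(x.max()) + 7):
                    ok = False
            if name == "gamma" and abs(t) > 5:  # gamma outside [e^-5, e^5]
                ok = False
            j += 1
        return ok


class EmaxRiskResults:
    """Fit results: estimates, uncertainty, and reporting.

    Attributes
    ----------
    params : EmaxParams
        Natural-scale estimates (fixed entries equal their mask values).
    nll : float
        Negative log-likelihood at the optimum.
    converged, identified : bool
        Optimizer status and boundary diagnostics.
    """

    def __init__(self, model: EmaxRiskModel, params: EmaxParams, mask: FixedMask,
                 theta: np.ndarray, nll: float, converged: bool, identified: bool,
                 options: FitOptions):
        self.model = model
        self.params = params
        self.mask = mask
        self.theta = np.asarray(theta, dtype=float)
        self.nll = nll
        self.converged = converged
        self.identified = identified
        self.options = options
        self._cov_internal: Optional[np.ndarray] = None
        self._cov_natural: Optional[np.ndarray] = None

    # -- basic accessors ----------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.model.nobs

    @property
    def n_events(self) -> int:
        return self.model.n_events

    @property
    def llf(self) -> float:
        return -self.nll

    @property
    def free_names(self) -> tuple:
        return self.mask.free_names

    def predict(self, x):
        """Predicted event probability at concentration(s) ``x`` (pg/mL)."""
        return emax_probability(x, self.params)

    # -- uncertainty --------------------------------------------------------
    def cov_internal(self) -> np.ndarray:
        """Variance-covariance of the free parameters on the internal
        (unconstrained) scale, from the finite-difference Hessian of the
        negative log-likelihood at the optimum."""
        if self._cov_internal is None:
            from .uncertainty import _internal_vcov
            self._cov_internal = _internal_vcov(self, rel_step=self.options.fd_rel_step)
        return self._cov_internal

    def cov_params(self) -> np.ndarray:
        """Natural-scale variance-covariance over the free parameters
        (delta method applied to the internal-scale covariance)."""
        if self._cov_natural is None:
            from .uncertainty import hessian_vcov
            self._cov_natural = hessian_vcov(
                (self.model.exog, self.model.endog), self,
                rel_step=self.options.fd_rel_step,
            )
        return self._cov_natural

    def bse(self) -> pd.Series:
        """Standard errors on the natural scale; 0 for fixed parameters."""
        se = pd.Series(0.0, index=list(PARAM_NAMES))
        cov = self.cov_params()
        se[list(self.free_names)] = np.sqrt(np.diag(cov))
        return se

    def conf_int(self, level: float = 0.90) -> pd.DataFrame:
        from .uncertainty import parameter_ci
        return parameter_ci(self, level=level)

    def risk_curve(self, grid=None, n_samples: int = 10_000, level: float = 0.90,
                   seed: int = 0):
        """Monte-Carlo propagated concentration-risk curve with CI band."""
        from .uncertainty import default_grid, propagate_curve
        grid = default_grid() if grid is None else grid
        return propagate_curve(self, self.cov_internal(), grid,
                               n_samples=n_samples, level=level, seed=seed)

    # -- reporting ----------------------------------------------------------
    def parameter_table(self, level: float = 0.90) -> pd.DataFrame:
        return self.conf_int(level=level)

    def summary(self, level: float = 0.90) -> str:
        table = self.parameter_table(level=level)
        lines = [
            "Emax risk model (Bernoulli maximum likelihood)",
            "=" * 58,
            f"N obs: {self.n_obs}    events: {self.n_events} "
            f"({100.0 * self.n_events / self.n_obs:.1f}%)",
            f"Log-likelihood: {self.llf:.4f}    converged: {self.converged}"
            f"    identified: {self.identified}",
            f"Free parameters: {', '.join(self.free_names)}",
            "-" * 58,
            table.to_string(float_format=lambda v: f"{v:.6g}"),
            "-" * 58,
            "Fixed parameters held at their stated values (se = 0).",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = self.params
        return (f"<EmaxRiskResults p0={p.p0:.4g} pmax={p.pmax:.4g} "
                f"ec50={p.ec50:.4g} gamma={p.gamma:.4g} nll={self.nll:.4g}>")


def fit_emax(rows, mask: Optional[FixedMask] = None,
             options: Optional[FitOptions] = None) -> EmaxRiskResults:
    """Fit the Emax risk function to analysis rows (functional front end)."""
    return EmaxRiskModel.from_rows(rows).fit(mask=mask, options=options)
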