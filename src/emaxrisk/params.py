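"""Saturating (Emax-type) concentration-risk function and its parameter space.

The model maps a plasma NT-proBNP concentration ``x`` (pg/mL) to the
probability of a composite clinical endpoint::

    P(x) = p0 + pmax * x**gamma / (x**gamma + ec50**gamma)

``p0`` is the baseline event probability at vanishing concentration, ``pmax``
the maximum probability added on top of the baseline, ``ec50`` the
concentration at half-maximum added risk, and ``gamma`` the Hill-type shape
exponent.  With ``p0 = 0`` and ``pmax = 1`` the function reduces to a
log-logistic response, i.e. a logistic function of ``gamma * (ln x - ln ec50)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["EmaxParams", "ParameterError", "emax_probability", "curve_table", "PARAM_NAMES"]

PARAM_NAMES = ("p0", "pmax", "ec50", "gamma")


class ParameterError(ValueError):
    """Raised when parameters or concentrations violate the model's domain."""


@dataclass(frozen=True)
class EmaxParams:
    """Parameters of the Emax risk function.

    Parameters
    ----------
    p0 : float
        Baseline event probability, in [0, 1].
    pmax : float
        Maximum probability added onto the baseline, in [0, 1];
        ``p0 + pmax`` must not exceed 1 so predictions stay probabilities.
    ec50 : float
        Concentration (pg/mL) at half-maximum added risk; strictly positive.
    gamma : float
        Shape (steepness) exponent; strictly positive.
    """

    p0: float
    pmax: float
    ec50: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ParameterError(f"p0 must lie in [0, 1], got {self.p0}")
        if not (0.0 <= self.pmax <= 1.0):
            raise ParameterError(f"pmax must lie in [0, 1], got {self.pmax}")
        if self.p0 + self.pmax > 1.0 + 1e-12:
            raise ParameterError(
                f"p0 + pmax must not exceed 1, got {self.p0 + self.pmax}"
            )
        if not (self.ec50 > 0.0 and np.isfinite(self.ec50)):
            raise ParameterError(f"ec50 must be finite and > 0, got {self.ec50}")
        if not (self.gamma > 0.0 and np.isfinite(self.gamma)):
            raise ParameterError(f"gamma must be finite and > 0, got {self.gamma}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.pmax, self.ec50, self.gamma], dtype=float)

    @classmethod
    def from_array(cls, values) -> "EmaxParams":
        p0, pmax, ec50, gamma = (float(v) for v in values)
        return cls(p0=p0, pmax=pmax, ec50=ec50, gamma=gamma)


def _validate_concentrations(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ParameterError("concentrations must be finite and >= 0")
    return x


def emax_probability(x, params: EmaxParams):
    """Event probability at concentration ``x`` (pg/mL).

    The saturating ratio is evaluated in log space,
    ``x**g / (x**g + ec50**g) = expit(g * (ln x - ln ec50))``, which is
    overflow-safe across concentrations spanning many orders of magnitude;
    ``x = 0`` is special-cased to the baseline ``p0``.

    Accepts a scalar or array ``x``; returns the same shape.
    """

    x = _validate_concentrations(x)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    ratio = np.zeros_like(xv)
    pos = xv > 0
    with np.errstate(divide="ignore"):
        ratio[pos] = expit(params.gamma * (np.log(xv[pos]) - np.log(params.ec50)))
    p = params.p0 + params.pmax * ratio
    return float(p[0]) if scalar else p


def curve_table(params: EmaxParams, grid) -> np.ndarray:
    """Tabulate the risk function on a strictly increasing concentration grid.

    Returns an ``(n, 2)`` array of (concentration, probability) rows; the
    probabilities are non-decreasing along the grid because the model is
    monotone in concentration.
    """

    grid = _validate_concentrations(grid)
    grid = np.atleast_1d(grid)
    if grid.size == 0:
        raise ParameterError("grid must be non-empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing")
    return np.column_stack([grid, emax_probability(grid, params)])
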