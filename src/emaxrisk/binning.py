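"""Model-free event rates in concentration quantile bins.

Patients are partitioned into quartiles/quintiles of the empirical NT-proBNP
distribution and the observed event rate per bin is reported with a Wilson
score binomial confidence interval, giving the stepped "observed data" curves
that a fitted model is judged against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .model import _as_xy
from .params import ParameterError

__all__ = ["BinnedRates", "bin_event_rates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinnedRates:
    """Quantile bins with empirical event rates and binomial CIs."""

    edges: np.ndarray     # len(bins) + 1 cut points, strictly increasing
    n: np.ndarray         # patients per bin
    events: np.ndarray    # events per bin
    rate: np.ndarray      # events / n
    lo: np.ndarray        # Wilson lower bound
    hi: np.ndarray        # Wilson upper bound
    level: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(self.events > self.n) or np.any(self.events < 0):
            raise ParameterError("0 <= events <= n must hold per bin")
        if np.any(self.lo > self.rate + 1e-12) or np.any(self.rate > self.hi + 1e-12):
            raise ParameterError("lo <= rate <= hi must hold per bin")

    @property
    def n_bins(self) -> int:
        return int(np.asarray(self.n).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "edge_lo": self.edges[:-1],
            "edge_hi": self.edges[1:],
            "n": self.n,
            "events": self.events,
            "rate": self.rate,
            "lo": self.lo,
            "hi": self.hi,
        })


def bin_event_rates(rows, n_bins: int, level: float = 0.90) -> BinnedRates:
    """Empirical event rates in quantile bins of concentration.

    Bins are defined by inverse-CDF empirical quantiles of the concentration
    distribution; an observation lying exactly on a cut point goes to the
    lower bin.  When ties collapse adjacent quantiles the duplicate edges are
    merged (fewer, wider bins) and a warning is logged.

    Parameters
    ----------
    rows : AnalysisRow sequence, DataFrame, or (concentrations, events) pair
    n_bins : int
        Number of quantile bins requested (>= 2, e.g. 4 for quartiles).
    level : float
        Two-sided Wilson score interval level, default 0.90.
    """

    x, y = _as_xy(rows)
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if x.size < n_bins:
        raise ParameterError("need at least one observation per bin")
    n_distinct = np.unique(x).size
    if n_bins > n_distinct:
        raise ParameterError(
            f"n_bins={n_bins} exceeds the {n_distinct} distinct concentrations; "
            f"use at most {n_distinct} bins"
        )
    if not (0.0 < level < 1.0):
        raise ParameterError("level must lie in (0, 1)")

    qs = np.arange(1, n_bins) / n_bins
    inner = np.quantile(x, qs, method="inverted_cdf").astype(float)
    inner = np.unique(inner)
    # A cut point at (or above) the maximum would leave the top bin empty, and
    # one at the minimum would make the bottom bin's edge pair degenerate.
    inner = inner[(inner < x.max()) & (inner > x.min())]
    if inner.size < n_bins - 1:
        logger.warning(
            "quantile ties reduced %d requested bins to %d", n_bins, inner.size + 1
        )

    idx = np.searchsorted(inner, x, side="left")
    k = inner.size + 1
    n = np.bincount(idx, minlength=k)
    events = np.bincount(idx, weights=y, minlength=k).astype(int)
    assert n.sum() == x.size

    rate = events / n
    lo, hi = proportion_confint(events, n, alpha=1.0 - level, method="wilson")
    edges = np.concatenate([[x.min()], inner, [x.max()]])
    return BinnedRates(edges=edges, n=n, events=events, rate=rate,
                       lo=np.asarray(lo, dtype=float), hi=np.asarray(hi, dtype=float),
                       level=level)
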