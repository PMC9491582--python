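"""Autocorrelation machinery shared by the shape and relaxation stages.

All estimators use the unbiased per-lag normalization: the raw lag sum
``S(t) = sum_tau x(tau) x(tau+t)`` is divided by the number of contributing
pairs ``n - t``.  Lag sums are evaluated with a zero-padded FFT
(Wiener-Khinchin), which is algebraically identical to the direct double
loop; tests assert the identity to 1e-10.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = ["CorrelationFunction", "autocorr_sums", "scalar_autocorrelation",
           "average_correlation", "log_lag_subsample"]


@dataclass
class CorrelationFunction:
    """A normalized time-correlation function on a uniform lag grid.

    Attributes
    ----------
    lags : ndarray
        Lag times in ps, starting at 0, uniformly spaced.
    values : ndarray
        Correlation values; ``values[0] == 1`` after normalization.
    n_source_series : int
        How many independent series were pooled into this estimate.
    truncation_fraction : float
        Fraction of the source-series length the lag grid was truncated to.
    """

    lags: np.ndarray
    values: np.ndarray
    n_source_series: int = 1
    truncation_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape or self.lags.ndim != 1:
            raise ValidationError("lags and values must be 1-D arrays of equal length")
        if self.lags[0] != 0.0:
            raise ValidationError("lag grid must start at 0")
        if len(self.lags) > 1:
            steps = np.diff(self.lags)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValidationError("lag grid must be strictly increasing and uniform")

    @property
    def frame_interval(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 0.0


def autocorr_sums(x: np.ndarray) -> np.ndarray:
    """Raw autocorrelation lag sums ``S(t) = sum_{tau} x[tau] x[tau+t]``.

    Computed for t = 0 .. n-1 via a zero-padded real FFT.  ``x`` may be
    (n,) or (n, k); component sums are accumulated over the trailing axis,
    which is what the P2 estimator needs for its quadratic components.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T  # (n, k)
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    s = np.fft.irfft((f * f.conj()).real.sum(axis=1), n=nfft)[:n]
    return s


def scalar_autocorrelation(
    values: np.ndarray,
    frame_interval: float,
    max_lag_fraction: float = 1.0 / 3.0,
) -> CorrelationFunction:
    """Offset-free, normalized autocorrelation of a scalar series.

    The global mean is subtracted once over the whole series; the result is
    ``C(t) = <dx(tau) dx(tau+t)> / <dx^2>`` with unbiased per-lag counts,
    reported for lags 0 .. max_lag_fraction * T.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need a 1-D series of length >= 2")
    n = len(x)
    dx = x - x.mean()
    s = autocorr_sums(dx)
    counts = n - np.arange(n)
    c = s / counts
    if c[0] <= 0.0:
        raise DegenerateInputError("series has zero variance; autocorrelation undefined")
    c /= c[0]
    n_lags = max(2, int(np.floor(max_lag_fraction * n)) + 1)
    n_lags = min(n_lags, n)
    lags = np.arange(n_lags) * float(frame_interval)
    return CorrelationFunction(lags, c[:n_lags], n_source_series=1,
                               truncation_fraction=max_lag_fraction)


def average_correlation(cfs: list[CorrelationFunction]) -> CorrelationFunction:
    """Pointwise mean of correlation functions on identical lag grids.

    Each input gets equal weight regardless of how many source series it
    already pools; ``n_source_series`` of the result is the sum.
    """
    if not cfs:
        raise ValidationError("need at least one correlation function")
    ref = cfs[0].lags
    for cf in cfs[1:]:
        if cf.lags.shape != ref.shape or not np.array_equal(cf.lags, ref):
            raise ValidationError("correlation functions must share an identical lag grid")
    values = np.mean([cf.values for cf in cfs], axis=0)
    return CorrelationFunction(
        ref.copy(),
        values,
        n_source_series=sum(cf.n_source_series for cf in cfs),
        truncation_fraction=cfs[0].truncation_fraction,
    )


def log_lag_subsample(n_lags: int, points_per_decade: int = 100) -> np.ndarray:
    """Deterministic log-spaced lag indices including 0 and the last lag.

    Multiexponential decays span decades in time; on a uniform lag grid
    almost all points sit in the longest decade, where a truncated
    correlation-function estimate is pure correlated noise, and a
    least-squares fit will buy residual there with spurious slow modes.
    Fitting on a logarithmic lag grid weights every decade equally, the
    standard practice for correlation-function fits.
    """
    if n_lags <= 2:
        return np.arange(n_lags)
    decades = np.log10(n_lags - 1)
    n_pts = max(2, int(np.ceil(points_per_decade * decades)))
    idx = np.unique(np.round(np.geomspace(1, n_lags - 1, n_pts)).astype(int))
    return np.concatenate([[0], idx])
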