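"""Regulatory time-lag estimation by unbiased cross-correlation.

For standardized profiles x_i (target) and x_j (candidate regulator) the
unbiased cross-correlation at lag τ is

    C(x_i, x_j, τ) = 1/(T−τ) · Σ_{t=1..T−τ} x_{t+τ,i} · x_{t,j},   τ = 0..r,

summed over every overlapping index pair.  τ is the delay by which the
regulator leads the target; only nonnegative lags are searched, so a lag of
0 means instantaneous association.  The most probable lag for the pair is
the τ that maximizes |C|; ties break toward the smallest (most
parsimonious) delay.

Two interchangeable routes compute the correlogram: a direct sliding dot
product and an FFT-based route (cross-correlation as inverse transform of
the conjugate spectral product); they agree to ~1e−15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data_io import ExpressionMatrix

__all__ = ["Correlogram", "cross_correlation", "infer_lags"]


@dataclass(frozen=True)
class Correlogram:
    """Unbiased cross-correlation values at lags 0..max_lag."""

    values: np.ndarray
    max_lag: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (self.max_lag + 1,):
            raise ValueError("correlogram length must be max_lag + 1")
        if not np.isfinite(self.values).all():
            raise ValueError("correlogram contains non-finite values")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.max_lag + 1)

    @property
    def best_lag(self) -> int:
        # argmax returns the first maximum, i.e. the smallest tying lag
        return int(np.argmax(np.abs(self.values)))


def _validate_pair(x_i: np.ndarray, x_j: np.ndarray, max_lag: int) -> int:
    if x_i.ndim != 1 or x_j.ndim != 1 or x_i.shape != x_j.shape:
        raise ValueError("profiles must be 1-D and of equal length")
    t = x_i.shape[0]
    if max_lag < 0:
        raise ValueError("max_lag must be nonnegative")
    if max_lag >= t - 1:
        raise ValueError(
            f"insufficient time points for lag range: need max_lag <= T-2, "
            f"got max_lag={max_lag}, T={t}"
        )
    return t


def cross_correlation(
    x_i: np.ndarray,
    x_j: np.ndarray,
    max_lag: int,
    route: str = "fft",
) -> Correlogram:
    """Correlogram of target profile ``x_i`` against regulator ``x_j``.

    Parameters
    ----------
    x_i, x_j : ndarray, shape (T,)
        Standardized expression profiles; ``x_i`` is the led (target) series
        and ``x_j`` the leading (regulator) series.
    max_lag : int
        Largest lag r searched; requires ``max_lag <= T - 2``.
    route : {"fft", "direct"}
        Numerical route; results agree to machine precision.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    t = _validate_pair(x_i, x_j, max_lag)
    norm = t - np.arange(max_lag + 1)
    if route == "direct":
        vals = np.array(
            [x_i[tau:] @ x_j[: t - tau] for tau in range(max_lag + 1)]
        )
    elif route == "fft":
        # full cross-correlation: index T-1+tau holds sum_t x_i[t+tau]*x_j[t]
        full = signal.correlate(x_i, x_j, mode="full", method="fft")
        vals = full[t - 1 : t + max_lag]
    else:
        raise ValueError(f"unknown route {route!r}")
    return Correlogram(vals / norm, max_lag)


def infer_lags(
    x: ExpressionMatrix | np.ndarray,
    target_index: int,
    max_lag: int,
    route: str = "fft",
) -> np.ndarray:
    """Most probable regulatory lag of every gene onto one target.

    For each candidate regulator j ≠ i returns
    argmax_{τ ∈ [0, max_lag]} |C(x_i, x_j, τ)|; the target's own entry is 0
    by convention.  The input matrix is expected to be standardized
    (see :func:`tdnd.data_io.normalize`); the argmax itself is invariant to
    positive rescaling of either profile.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    n = values.shape[1]
    if not 0 <= target_index < n:
        raise ValueError(f"target_index {target_index} out of range for N={n}")
    lags = np.zeros(n, dtype=int)
    xi = values[:, target_index]
    for j in range(n):
        if j == target_index:
            continue
        lags[j] = cross_correlation(xi, values[:, j], max_lag, route).best_lag
    return lags
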