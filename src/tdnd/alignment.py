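"""Lag-based alignment of time samples for one target gene.

With maximum searched lag r, each unit of lag costs one usable sample: the
target contributes its last T−r observations and each candidate regulator j
contributes the window shifted back by its inferred lag l_ij,

    y   = X[r+1 .. T,          i]      (target, 1-based inclusive)
    x_j = X[r−l_ij+1 .. T−l_ij, j]     (regulator)

so that row k of the aligned matrix pairs the target at time r+k with each
regulator at time r+k−l_ij.  For periodic series a circular mode instead
rotates each regulator column by its lag, keeping all T samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

__all__ = ["AlignedMatrix", "align_samples"]


@dataclass(frozen=True)
class AlignedMatrix:
    """Lag-aligned samples for one target gene.

    ``values`` has T−r rows in linear mode (T in circular mode) and one
    column per gene, target included, in the original gene order.
    """

    values: np.ndarray
    target_index: int
    lags: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def align_samples(
    x: ExpressionMatrix | np.ndarray,
    lags: np.ndarray,
    target_index: int,
    max_lag: int,
    mode: str = "linear",
) -> AlignedMatrix:
    """Build the aligned sample matrix for ``target_index``.

    Parameters
    ----------
    x : ExpressionMatrix or ndarray (T, N)
        Standardized expression matrix.
    lags : int array, shape (N,)
        Inferred lag of each gene onto the target; entries in [0, max_lag].
    max_lag : int
        The lag bound r that was searched; fixes the common window length.
    mode : {"linear", "circular"}
        ``linear`` (default, non-periodic data) yields T−r rows; ``circular``
        (periodic data) rotates columns and keeps all T rows.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    t, n = values.shape
    lags = np.asarray(lags)
    if lags.shape != (n,):
        raise ValueError(f"lag vector must have length N={n}")
    if not np.issubdtype(lags.dtype, np.integer):
        raise ValueError("lags must be integers")
    if (lags < 0).any() or (lags > max_lag).any():
        raise ValueError(
            f"lags must lie in [0, {max_lag}]; got range "
            f"[{lags.min()}, {lags.max()}]"
        )
    if not 0 <= target_index < n:
        raise ValueError(f"target_index {target_index} out of range for N={n}")
    if mode == "linear":
        if max_lag >= t:
            raise ValueError(f"max_lag={max_lag} must be smaller than T={t}")
        aligned = np.empty((t - max_lag, n))
        for j in range(n):
            l = 0 if j == target_index else int(lags[j])
            # 1-based window r−l+1..T−l  ->  0-based slice r−l : t−l
            aligned[:, j] = values[max_lag - l : t - l, j]
    elif mode == "circular":
        aligned = np.empty((t, n))
        for j in range(n):
            l = 0 if j == target_index else int(lags[j])
            aligned[:, j] = np.roll(values[:, j], l)
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return AlignedMatrix(aligned, int(target_index), lags.copy())
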