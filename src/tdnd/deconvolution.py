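"""Spectral network deconvolution.

An observed similarity matrix S_o is modelled as the sum of direct effects
and all transitive (indirect) paths through them,

    S_o = S_d + S_d² + S_d³ + ... = S_d (I − S_d)⁻¹,

which converges when the spectral radius of S_d is below one.  Because S_o
and S_d share eigenvectors, the inverse problem is solved in closed form on
the spectrum: each observed eigenvalue maps to a direct one by

    λ_d = λ_o / (1/α + λ_o),

where α = 1 recovers the exact inverse S_d = S_o (I + S_o)⁻¹.  To guarantee
a convergent (|λ_d| < 1) result on arbitrary inputs the shift 1/α is, by
default, chosen so the mapped spectrum has largest absolute eigenvalue β
(default 0.5), the convention of the reference implementation of network
deconvolution.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

__all__ = ["deconvolve", "observed_from_direct", "rescale_weights"]

_SYM_TOL = 1e-10


def _check_square_symmetric(s: np.ndarray, name: str) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"{name} must be square, got shape {s.shape}")
    if not np.isfinite(s).all():
        raise ValueError(f"{name} contains non-finite values")
    asym = np.abs(s - s.T).max(initial=0.0)
    if asym > _SYM_TOL:
        raise ValueError(
            f"{name} is not symmetric (max |S - S.T| = {asym:.3g}); "
            "asymmetric deconvolution is not implemented"
        )
    return (s + s.T) / 2.0


def observed_from_direct(s_d: np.ndarray) -> np.ndarray:
    """Forward model: observed matrix from a direct-dependency matrix.

    Computes S_d (I − S_d)⁻¹, the closed form of the geometric series of
    transitive effects.  Requires spectral radius of ``s_d`` strictly < 1.
    """
    s_d = _check_square_symmetric(s_d, "S_d")
    rho = np.abs(linalg.eigvalsh(s_d)).max(initial=0.0)
    if rho >= 1.0:
        raise ValueError(
            f"series does not converge: spectral radius {rho:.6g} >= 1"
        )
    n = s_d.shape[0]
    s_o = s_d @ np.linalg.inv(np.eye(n) - s_d)
    return (s_o + s_o.T) / 2.0


def deconvolve(
    s_o: np.ndarray,
    alpha: float | None = None,
    beta: float = 0.5,
) -> np.ndarray:
    """Recover the direct-dependency matrix from an observed one.

    Parameters
    ----------
    s_o : ndarray (N, N)
        Symmetric observed similarity matrix.
    alpha : float, optional
        Explicit scaling factor; the eigenvalue map is
        λ_d = λ_o / (1/alpha + λ_o).  ``alpha=1`` is the exact inverse of
        :func:`observed_from_direct`.  When None (default) the shift is set
        from ``beta`` instead.
    beta : float in (0, 1)
        Target largest absolute eigenvalue of the output; used only when
        ``alpha`` is None.

    Returns
    -------
    ndarray (N, N)
        Symmetric direct matrix with the same eigenvectors as the input.
    """
    s_o = _check_square_symmetric(s_o, "S_o")
    w, u = linalg.eigh(s_o)
    if alpha is not None:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        shift = 1.0 / float(alpha)
        if np.any(np.abs(shift + w) < 1e-12):
            raise ValueError(
                "eigenvalue at the pole of the deconvolution map "
                f"(1/alpha + lambda ~ 0 with alpha={alpha})"
            )
    else:
        if not 0.0 < beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        lam_p = max(w.max(initial=0.0), 0.0)
        lam_n = abs(min(w.min(initial=0.0), 0.0))
        shift = max(lam_p * (1.0 - beta) / beta, lam_n * (1.0 + beta) / beta)
        if shift == 0.0:  # zero matrix: nothing to map
            return np.zeros_like(s_o)
    w_d = w / (shift + w)
    s_d = (u * w_d) @ u.T
    return (s_d + s_d.T) / 2.0


def rescale_weights(s: np.ndarray) -> np.ndarray:
    """Map off-diagonal interaction strengths affinely onto [0, 1].

    Takes absolute values (strength, not sign), sends the global off-diagonal
    minimum to 0 and maximum to 1, and forces the diagonal to 0.  A matrix
    whose off-diagonal entries are all equal is uninformative and maps to all
    zeros with a warning.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {s.shape}")
    if not np.isfinite(s).all():
        raise ValueError("weight matrix contains non-finite values")
    a = np.abs(s).copy()
    np.fill_diagonal(a, 0.0)
    off = a[~np.eye(a.shape[0], dtype=bool)]
    lo, hi = off.min(), off.max()
    if hi - lo < 1e-300:
        warnings.warn(
            "all off-diagonal weights are equal; rescaled matrix is all zeros",
            stacklevel=2,
        )
        return np.zeros_like(a)
    scaled = (a - lo) / (hi - lo)
    np.fill_diagonal(scaled, 0.0)
    return scaled
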