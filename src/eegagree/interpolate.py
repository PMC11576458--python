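"""Spherical-spline scalp interpolation (Perrin-style).

Bad channels are reconstructed from the remaining good channels using
spherical splines on unit-sphere electrode positions: the surface
potential is modeled as v(x) = c0 + sum_i c_i g(cos(x, x_i)) with

    g(x) = (1/4pi) * sum_{n=1}^{N} (2n+1) / (n(n+1))^m * P_n(x)

where P_n are Legendre polynomials, m is the spline order (stiffness) and
the series is truncated at degree N.  A small ridge term regularizes the
solve.  Splines reproduce constant fields exactly through the c0 term.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre


def _g_matrix(cosang: np.ndarray, m: int, degree: int) -> np.ndarray:
    n = np.arange(1, degree + 1)
    coeffs = np.zeros(degree + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def interpolation_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    m: int = 4,
    degree: int = 7,
    lam: float = 1e-5,
) -> np.ndarray:
    """Matrix W such that ``v_bad = W @ v_good`` under the spline model.

    Parameters
    ----------
    pos_good, pos_bad : arrays of shape (k, 3) / (b, 3)
        Unit-sphere electrode positions.
    m : int
        Spline order (interpolation stiffness).
    degree : int
        Truncation degree of the Legendre series.
    lam : float
        Ridge regularization added to the diagonal of the spline system.
    """
    pos_good = np.asarray(pos_good, float)
    pos_bad = np.asarray(pos_bad, float)
    pos_good = pos_good / np.linalg.norm(pos_good, axis=1, keepdims=True)
    pos_bad = pos_bad / np.linalg.norm(pos_bad, axis=1, keepdims=True)
    k = pos_good.shape[0]
    if k < 4:
        raise ValueError("need at least 4 good channels for interpolation")

    G = _g_matrix(pos_good @ pos_good.T, m, degree)
    Gb = _g_matrix(pos_bad @ pos_good.T, m, degree)

    # solve [[G + lam*I, 1], [1^T, 0]] [c; mu] = [v; 0]
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G + lam * np.eye(k)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    Ainv = np.linalg.pinv(A)
    # v_bad = [Gb, 1] @ [c; mu] and [c; mu] = Ainv[:, :k] @ v
    B = np.hstack([Gb, np.ones((pos_bad.shape[0], 1))])
    return B @ Ainv[:, :k]
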