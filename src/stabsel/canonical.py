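"""Canonical analysis of the nonlinear selection matrix.

Interpreting individual gamma coefficients understates multivariate
nonlinear selection; rotating the traits onto the eigenvectors of gamma
concentrates all curvature on orthogonal axes. Each eigenvector m_i
carries pure quadratic selection of strength lambda_i (its eigenvalue:
negative = stabilizing, positive = disruptive), and the linear gradient
along the axis, theta_i, is obtained either by projecting beta onto m_i
or by the double-regression method (refit fitness on the rotated scores
and their squares). The two agree for symmetrically distributed traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DataError

__all__ = [
    "CanonicalDecomposition",
    "canonical_rotation",
    "theta_projection",
    "double_regression",
    "canonical_decomposition",
]


@dataclass
class CanonicalDecomposition:
    """Eigenvectors (rows of M), eigenvalues, and linear gradients theta.

    Axes are ordered by descending eigenvalue, so the most stabilizing
    axes (largest negative curvature) come last. ``theta_method``
    records how theta was computed: ``projection`` or
    ``double_regression``.
    """

    M: np.ndarray
    lam: np.ndarray
    theta: np.ndarray | None = None
    theta_method: str | None = None

    def __post_init__(self) -> None:
        p = self.M.shape[0]
        if np.linalg.norm(self.M @ self.M.T - np.eye(p)) > 1e-10:
            raise DataError("eigenvector rows must be orthonormal")


def _symmetrize(gamma: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise DataError("gamma must be square")
    if np.abs(gamma - gamma.T).max() > tol:
        raise DataError("gamma is asymmetric beyond tolerance")
    return 0.5 * (gamma + gamma.T)


def canonical_rotation(gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose gamma into axes of pure curvature.

    Returns (M, lam): rows of M are unit eigenvectors sorted by
    descending eigenvalue. The sign of each row is fixed so its
    largest-magnitude loading is positive; eigenvectors are only
    defined up to sign, so comparisons with published loadings should
    be made up to sign.
    """
    g = _symmetrize(gamma)
    lam, vec = np.linalg.eigh(g)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    M = vec[:, order].T
    for i in range(M.shape[0]):
        k = np.argmax(np.abs(M[i]))
        if M[i, k] < 0:
            M[i] = -M[i]
    return M, lam


def theta_projection(M: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Linear selection along each axis: theta_i = m_i . beta."""
    M = np.asarray(M, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if M.shape[1] != beta.shape[0]:
        raise DataError("eigenvector and beta dimensions do not match")
    return M @ beta


def double_regression(
    Z: np.ndarray, w: np.ndarray, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Re-estimate linear and quadratic selection along fixed axes.

    Fits relative fitness on the rotated scores y_i = (Z M^T)_i and
    their squares in one regression. Returns (theta, lambda_refit) with
    the squared-term coefficients doubled, on the same scale as the
    canonical eigenvalues.
    """
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(w, dtype=float)
    M = np.asarray(M, dtype=float)
    p = M.shape[0]
    if np.linalg.norm(M @ M.T - np.eye(p)) > 1e-8:
        raise DataError("M must be orthonormal")
    n = Z.shape[0]
    if n <= 2 * p + 1:
        raise DataError(f"double regression needs n > {2 * p + 1}")
    Y = Z @ M.T
    X = np.column_stack([np.ones(n), Y, Y**2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("double-regression design is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, w, rcond=None)
    theta = coef[1 : 1 + p]
    lam_refit = 2.0 * coef[1 + p :]
    return theta, lam_refit


def canonical_decomposition(
    gamma: np.ndarray,
    beta: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    w: np.ndarray | None = None,
    theta_method: str = "projection",
) -> CanonicalDecomposition:
    """Full canonical analysis with theta by the requested method."""
    M, lam = canonical_rotation(gamma)
    theta = None
    if theta_method == "projection":
        if beta is not None:
            theta = theta_projection(M, beta)
    elif theta_method == "double_regression":
        if Z is None or w is None:
            raise DataError("double_regression needs Z and w")
        theta, _ = double_regression(Z, w, M)
    else:
        raise DataError(f"unknown theta method {theta_method!r}")
    return CanonicalDecomposition(M=M, lam=lam, theta=theta,
                                  theta_method=theta_method if theta is not None
                                  else None)
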