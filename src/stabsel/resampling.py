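"""Permutation inference for selection gradients.

Relative fitness built from a binary outcome is far from normal, so
gradient significance is assessed by randomization: fitness scores are
shuffled across pairs (traits untouched, so the male-female pairing is
preserved), the full regression model is refit on each shuffle, and the
proportion p of pseudo-estimates less than or equal to the observed
gradient is converted to a two-tailed probability with Manly's rule:
2p if p < 0.5, 2(1 - p) if p > 0.5, and 1 at p = 0.5.

Because only the response is permuted, every null refit shares the
design matrix, so all iterations reduce to one matrix product with the
precomputed pseudo-inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DataError
from .gradients import (
    Term,
    coefficients_to_gradients,
    cross_sex_design,
    linear_design,
    quadratic_design,
)

__all__ = [
    "PermutationResult",
    "manly_two_tailed",
    "permute_gradient_pvalues",
    "reynolds_lambda_test",
]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the two-tailed p."""

    term: Term
    observed: float
    null_values: np.ndarray
    proportion: float
    p_two_tailed: float
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_tailed <= 1.0):
            raise DataError("two-tailed p must lie in (0, 1]")
        if len(self.null_values) != self.n_iter:
            raise DataError("null distribution length must equal n_iter")


def manly_two_tailed(proportion: float, n_iter: int | None = None) -> float:
    """Two-tailed p from the one-sided proportion of null values <= observed.

    When ``n_iter`` is given, proportions of exactly 0 or 1 (no or all
    pseudo-estimates at or below the observed value) are clamped to
    1/n_iter and 1 - 1/n_iter before doubling, so the smallest
    reportable p is 2/n_iter rather than an uninformative 0.
    """
    if not (0.0 <= proportion <= 1.0):
        raise DataError(f"proportion must lie in [0, 1]; got {proportion}")
    if n_iter is not None:
        lo = 1.0 / n_iter
        proportion = min(max(proportion, lo), 1.0 - lo)
    if proportion < 0.5:
        return 2.0 * proportion
    if proportion > 0.5:
        return 2.0 * (1.0 - proportion)
    return 1.0


def _permutation_nulls(
    X: np.ndarray, w: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Coefficients of the model refit on n_iter shuffles of w.

    Returns an (n_terms, n_iter) array (intercept included as row 0).
    """
    W = np.empty((len(w), n_iter))
    for b in range(n_iter):
        W[:, b] = rng.permutation(w)
    pinv = np.linalg.pinv(X)
    return pinv @ W


def permute_gradient_pvalues(
    Z,
    w: np.ndarray,
    model: str = "linear",
    n_iter: int = 10_000,
    seed: int = 0,
    trait_names=None,
) -> list[PermutationResult]:
    """Permutation p-values for every gradient in one regression model.

    ``model`` selects the regression: ``linear`` (first-order),
    ``quadratic`` (full second-order), or ``cross_sex`` (two-sex model,
    in which case ``Z`` is the pair ``(Z_male, Z_female)`` and
    ``trait_names`` the pair of name lists). Quadratic pseudo-estimates
    are doubled exactly like the observed gradients, so observed and
    null values are on the same scale.
    """
    if n_iter < 100:
        raise DataError("n_iter must be at least 100")
    w = np.asarray(w, dtype=float)

    if model == "linear":
        Z = np.asarray(Z, dtype=float)
        names = list(trait_names) if trait_names is not None else [
            f"trait_{j}" for j in range(Z.shape[1])
        ]
        X, terms = linear_design(Z, names)
    elif model == "quadratic":
        Z = np.asarray(Z, dtype=float)
        names = list(trait_names) if trait_names is not None else [
            f"trait_{j}" for j in range(Z.shape[1])
        ]
        X, terms = quadratic_design(Z, names)
    elif model == "cross_sex":
        Z_m, Z_f = (np.asarray(a, dtype=float) for a in Z)
        if trait_names is not None:
            names_m, names_f = (list(a) for a in trait_names)
        else:
            names_m = [f"trait_{j}" for j in range(Z_m.shape[1])]
            names_f = [f"trait_{j}" for j in range(Z_f.shape[1])]
        X, terms = cross_sex_design(Z_m, Z_f, names_m, names_f)
    else:
        raise DataError(f"unknown model {model!r}")

    if X.shape[0] != len(w):
        raise DataError("fitness vector length does not match trait matrix")
    if X.shape[0] <= X.shape[1]:
        raise DataError(
            f"model has {X.shape[1]} parameters; need n > {X.shape[1]}"
        )

    observed_coef = np.linalg.pinv(X) @ w
    observed = coefficients_to_gradients(observed_coef[1:], terms)

    rng = np.random.default_rng(seed)
    nulls = _permutation_nulls(X, w, n_iter, rng)[1:]  # drop intercept row
    for k, t in enumerate(terms):
        if t.kind == "quadratic":
            nulls[k] *= 2.0

    results = []
    for k, t in enumerate(terms):
        prop = float(np.mean(nulls[k] <= observed[k]))
        results.append(
            PermutationResult(
                term=t,
                observed=float(observed[k]),
                null_values=nulls[k].copy(),
                proportion=prop,
                p_two_tailed=manly_two_tailed(prop, n_iter),
                n_iter=n_iter,
                seed=seed,
            )
        )
    return results


def reynolds_lambda_test(
    Z: np.ndarray,
    w: np.ndarray,
    M: np.ndarray,
    n_iter: int = 10_000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Permutation test for curvature along fixed canonical axes.

    The rotated scores Y = Z M^T are computed once from the observed
    eigenvector matrix M and held fixed; each iteration shuffles w and
    refits the double-regression model (all y_i and y_i² terms jointly),
    recording each axis's doubled squared-term coefficient. Keeping M
    fixed avoids the upward bias in |lambda| that re-diagonalizing a
    re-estimated gamma under the null would introduce.
    """
    if n_iter < 100:
        raise DataError("n_iter must be at least 100")
    Z = np.asarray(Z, dtype=float)
    M = np.asarray(M, dtype=float)
    w = np.asarray(w, dtype=float)
    p = M.shape[0]
    if np.linalg.norm(M @ M.T - np.eye(p)) > 1e-8:
        raise DataError("M must be orthonormal (rows are unit eigenvectors)")

    Y = Z @ M.T
    n = Y.shape[0]
    X = np.column_stack([np.ones(n), Y, Y**2])
    terms = [Term("quadratic", f"m{i + 1}") for i in range(p)]

    pinv = np.linalg.pinv(X)
    observed = 2.0 * (pinv @ w)[1 + p:]

    rng = np.random.default_rng(seed)
    nulls = 2.0 * _permutation_nulls(X, w, n_iter, rng)[1 + p:]

    results = []
    for k in range(p):
        prop = float(np.mean(nulls[k] <= observed[k]))
        results.append(
            PermutationResult(
                term=terms[k],
                observed=float(observed[k]),
                null_values=nulls[k].copy(),
                proportion=prop,
                p_two_tailed=manly_two_tailed(prop, n_iter),
                n_iter=n_iter,
                seed=seed,
            )
        )
    return results
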