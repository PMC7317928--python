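"""Standardized linear, quadratic, and correlational selection gradients.

Selection gradients are partial regression coefficients of relative
fitness on standardized traits (Lande-Arnold analysis). The linear
gradient vector beta comes from a first-order multiple regression; the
nonlinear matrix gamma comes from a separate second-order regression
containing all linear, squared, and cross-product terms. Squared-term
coefficients are doubled (the quadratic regression coefficient
understates the curvature of the fitness surface by a factor of two);
cross-product coefficients enter gamma as estimated.

Fitting is ordinary least squares on relative fitness derived from the
binary outcome (a linear probability model). OLS standard errors are
never used for inference — significance comes from permutation
(:mod:`stabsel.resampling`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import DataError

__all__ = [
    "GradientSet",
    "InteractionMatrix",
    "Term",
    "linear_gradients",
    "quadratic_gradients",
    "fit_gradients",
    "cross_sex_model",
    "gradient_correlation",
]


@dataclass(frozen=True)
class Term:
    """One regression term: its class and the trait(s) it involves.

    ``kind`` is one of ``linear``, ``quadratic``, ``correlational``,
    ``cross_sex``. For cross-sex terms ``trait_1`` is the female trait
    and ``trait_2`` the male trait.
    """

    kind: str
    trait_1: str
    trait_2: str | None = None

    def label(self) -> str:
        if self.trait_2 is None:
            return f"{self.kind}:{self.trait_1}"
        return f"{self.kind}:{self.trait_1}:{self.trait_2}"


@dataclass
class GradientSet:
    """Estimated selection gradients for one sex.

    gamma is symmetric with the doubled quadratic gradients on the
    diagonal and correlational gradients off the diagonal. r-squared
    values are reported for the first-order (beta) and second-order
    (gamma) models separately.
    """

    beta: np.ndarray
    gamma: np.ndarray
    r2_linear: float
    r2_quadratic: float
    n: int
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.allclose(self.gamma, self.gamma.T, atol=1e-12):
            raise DataError("gamma must be symmetric")


@dataclass
class InteractionMatrix:
    """Cross-sex correlational selection gradients.

    ``values[i, j]`` is the gradient on the product of female trait i
    and male trait j: selection on the covariance between the sexes.
    """

    values: np.ndarray
    female_names: list[str]
    male_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.female_names), len(self.male_names)):
            raise DataError("interaction matrix shape does not match trait names")
        if not np.isfinite(self.values).all():
            raise DataError("interaction matrix contains non-finite values")


# ---------------------------------------------------------------------------
# design matrices


def linear_design(Z: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[Term]]:
    """Design matrix [1 | z] and term metadata for the first-order model."""
    n = Z.shape[0]
    X = np.column_stack([np.ones(n), Z])
    terms = [Term("linear", nm) for nm in names]
    return X, terms


def quadratic_design(
    Z: np.ndarray, names: list[str]
) -> tuple[np.ndarray, list[Term]]:
    """Design [1 | z | z^2 | z_i z_j (i<j)] and term metadata."""
    n, p = Z.shape
    cols = [np.ones(n)]
    terms: list[Term] = []
    for j in range(p):
        cols.append(Z[:, j])
        terms.append(Term("linear", names[j]))
    for j in range(p):
        cols.append(Z[:, j] ** 2)
        terms.append(Term("quadratic", names[j]))
    for i in range(p):
        for j in range(i + 1, p):
            cols.append(Z[:, i] * Z[:, j])
            terms.append(Term("correlational", names[i], names[j]))
    return np.column_stack(cols), terms


def cross_sex_design(
    Z_male: np.ndarray,
    Z_female: np.ndarray,
    male_names: list[str],
    female_names: list[str],
) -> tuple[np.ndarray, list[Term]]:
    """Full two-sex second-order design with all between-sex products.

    Terms per sex get name prefixes ``male:``/``female:`` so both sexes
    can share trait labels. Between-sex products are tagged
    ``cross_sex`` with (female trait, male trait) order.
    """
    if Z_male.shape[0] != Z_female.shape[0]:
        raise DataError("male and female matrices must describe the same pairs")
    Xm, terms_m = quadratic_design(Z_male, [f"male:{n}" for n in male_names])
    Xf, terms_f = quadratic_design(Z_female, [f"female:{n}" for n in female_names])
    cols = [Xm, Xf[:, 1:]]  # drop duplicate intercept
    terms = terms_m + terms_f
    cross_cols = []
    cross_terms = []
    for i, fn in enumerate(female_names):
        for j, mn in enumerate(male_names):
            cross_cols.append(Z_female[:, i] * Z_male[:, j])
            cross_terms.append(Term("cross_sex", f"female:{fn}", f"male:{mn}"))
    cols.append(np.column_stack(cross_cols))
    return np.column_stack(cols), terms + cross_terms


# ---------------------------------------------------------------------------
# OLS core


def _check_rank(X: np.ndarray, term_names: list[str]) -> None:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        labels = [term_names[k] for k in bad]
        raise DataError(f"design matrix is rank deficient; collinear columns: {labels}")


def ols_fit(X: np.ndarray, y: np.ndarray, term_names: list[str] | None = None
            ) -> tuple[np.ndarray, float]:
    """Least-squares fit returning coefficients and r-squared.

    r-squared is 0 by convention when y has no variance.
    """
    if term_names is None:
        term_names = [f"col_{j}" for j in range(X.shape[1])]
    if X.shape[0] <= X.shape[1]:
        raise DataError(
            f"need more than {X.shape[1]} observations to fit "
            f"{X.shape[1]} parameters; got {X.shape[0]}"
        )
    _check_rank(X, term_names)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return coef, r2


def coefficients_to_gradients(coef: np.ndarray, terms: list[Term]) -> np.ndarray:
    """Map raw OLS coefficients to reported gradients (double the squares)."""
    out = coef.copy()
    for k, t in enumerate(terms):
        if t.kind == "quadratic":
            out[k] = 2.0 * coef[k]
    return out


# ---------------------------------------------------------------------------
# public estimators


def linear_gradients(
    Z: np.ndarray, w: np.ndarray, trait_names: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Standardized linear selection gradients beta and the model r²."""
    Z = np.asarray(Z, dtype=float)
    names = trait_names or [f"trait_{j}" for j in range(Z.shape[1])]
    X, terms = linear_design(Z, names)
    coef, r2 = ols_fit(X, np.asarray(w, float),
                       ["intercept"] + [t.label() for t in terms])
    return coef[1:], r2


def quadratic_gradients(
    Z: np.ndarray, w: np.ndarray, trait_names: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Nonlinear gradient matrix gamma and the second-order model r².

    The diagonal holds doubled squared-term coefficients; off-diagonals
    hold cross-product coefficients as estimated. Linear coefficients
    from this model are discarded (beta is reported from the
    first-order model).
    """
    Z = np.asarray(Z, dtype=float)
    p = Z.shape[1]
    names = trait_names or [f"trait_{j}" for j in range(p)]
    X, terms = quadratic_design(Z, names)
    coef, r2 = ols_fit(X, np.asarray(w, float),
                       ["intercept"] + [t.label() for t in terms])
    grads = coefficients_to_gradients(coef[1:], terms)
    gamma = np.zeros((p, p))
    name_index = {nm: j for j, nm in enumerate(names)}
    for g, t in zip(grads, terms):
        if t.kind == "quadratic":
            j = name_index[t.trait_1]
            gamma[j, j] = g
        elif t.kind == "correlational":
            i, j = name_index[t.trait_1], name_index[t.trait_2]
            gamma[i, j] = gamma[j, i] = g
    return gamma, r2


def fit_gradients(
    Z: np.ndarray, w: np.ndarray, trait_names: list[str] | None = None
) -> GradientSet:
    """Convenience: beta from the first-order model, gamma from the second."""
    names = trait_names or [f"trait_{j}" for j in range(np.shape(Z)[1])]
    beta, r2_lin = linear_gradients(Z, w, names)
    gamma, r2_quad = quadratic_gradients(Z, w, names)
    return GradientSet(beta=beta, gamma=gamma, r2_linear=r2_lin,
                       r2_quadratic=r2_quad, n=np.shape(Z)[0],
                       trait_names=list(names))


def cross_sex_model(
    Z_male: np.ndarray,
    Z_female: np.ndarray,
    w: np.ndarray,
    male_names: list[str] | None = None,
    female_names: list[str] | None = None,
) -> tuple[GradientSet, GradientSet, InteractionMatrix]:
    """Joint two-sex model with all between-sex cross products.

    beta per sex comes from a first-order model on the concatenated
    traits of both sexes; gamma per sex and the female-by-male
    interaction block come from the full second-order model. With p
    traits per sex the second-order model has 1 + 2p + 2p + p(p-1)
    + p² parameters (66 for p = 5), and n must exceed that count.
    """
    Z_male = np.asarray(Z_male, dtype=float)
    Z_female = np.asarray(Z_female, dtype=float)
    w = np.asarray(w, dtype=float)
    p_m, p_f = Z_male.shape[1], Z_female.shape[1]
    male_names = male_names or [f"trait_{j}" for j in range(p_m)]
    female_names = female_names or [f"trait_{j}" for j in range(p_f)]

    X, terms = cross_sex_design(Z_male, Z_female, male_names, female_names)
    n_params = X.shape[1]
    if Z_male.shape[0] <= n_params:
        raise DataError(
            f"two-sex second-order model needs n > {n_params}; "
            f"got n = {Z_male.shape[0]}"
        )

    # first-order model on both sexes jointly for the beta vectors
    Z_all = np.column_stack([Z_male, Z_female])
    all_names = [f"male:{n}" for n in male_names] + [
        f"female:{n}" for n in female_names
    ]
    beta_all, r2_lin = linear_gradients(Z_all, w, all_names)
    beta_m, beta_f = beta_all[:p_m], beta_all[p_m:]

    coef, r2_quad = ols_fit(X, w, ["intercept"] + [t.label() for t in terms])
    grads = coefficients_to_gradients(coef[1:], terms)

    gamma_m = np.zeros((p_m, p_m))
    gamma_f = np.zeros((p_f, p_f))
    inter = np.zeros((p_f, p_m))
    idx_m = {f"male:{nm}": j for j, nm in enumerate(male_names)}
    idx_f = {f"female:{nm}": j for j, nm in enumerate(female_names)}
    for g, t in zip(grads, terms):
        if t.kind == "quadratic":
            if t.trait_1 in idx_m:
                j = idx_m[t.trait_1]
                gamma_m[j, j] = g
            else:
                j = idx_f[t.trait_1]
                gamma_f[j, j] = g
        elif t.kind == "correlational":
            if t.trait_1 in idx_m:
                i, j = idx_m[t.trait_1], idx_m[t.trait_2]
                gamma_m[i, j] = gamma_m[j, i] = g
            else:
                i, j = idx_f[t.trait_1], idx_f[t.trait_2]
                gamma_f[i, j] = gamma_f[j, i] = g
        elif t.kind == "cross_sex":
            inter[idx_f[t.trait_1], idx_m[t.trait_2]] = g

    n = Z_male.shape[0]
    set_m = GradientSet(beta_m, gamma_m, r2_lin, r2_quad, n, list(male_names))
    set_f = GradientSet(beta_f, gamma_f, r2_lin, r2_quad, n, list(female_names))
    return set_m, set_f, InteractionMatrix(inter, list(female_names),
                                           list(male_names))


def gradient_correlation(
    sets_a: tuple[GradientSet, GradientSet],
    sets_b: tuple[GradientSet, GradientSet],
) -> dict[str, dict[str, float]]:
    """Pearson correlation between two analyses' gradients, by element class.

    Used to check that a joint two-sex model leaves the per-sex gradients
    essentially unchanged relative to the conventional one-sex models.
    Classes pool both sexes: linear (p_m + p_f elements), quadratic
    (diagonal, p_m + p_f), and within-sex correlational (the strict
    lower triangles, p_m(p_m-1)/2 + p_f(p_f-1)/2).
    """
    am, af = sets_a
    bm, bf = sets_b
    if am.trait_names != bm.trait_names or af.trait_names != bf.trait_names:
        raise DataError("gradient sets have mismatched trait structure")

    def tril(g: np.ndarray) -> np.ndarray:
        i, j = np.tril_indices_from(g, k=-1)
        return g[i, j]

    classes = {
        "linear": (np.concatenate([am.beta, af.beta]),
                   np.concatenate([bm.beta, bf.beta])),
        "quadratic": (np.concatenate([np.diag(am.gamma), np.diag(af.gamma)]),
                      np.concatenate([np.diag(bm.gamma), np.diag(bf.gamma)])),
        "correlational": (np.concatenate([tril(am.gamma), tril(af.gamma)]),
                          np.concatenate([tril(bm.gamma), tril(bf.gamma)])),
    }
    report: dict[str, dict[str, float]] = {}
    for name, (a, b) in classes.items():
        r, p = stats.pearsonr(a, b)
        report[name] = {"r": float(r), "p": float(p), "n": int(a.size)}
    return report
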