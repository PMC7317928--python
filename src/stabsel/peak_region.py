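"""Fitness-surface optimum and its nonparametric bootstrap confidence region.

A negative quadratic gradient alone does not establish stabilizing
selection: the fitness peak must also lie inside the sampled phenotypic
range. This module locates the global maximum of the fitness surface in
a chosen (typically two-dimensional canonical) trait subspace and
attaches a 95% confidence region built by residual bootstrapping:

1. fit a quadratic polynomial surface by OLS and keep its residuals;
2. for each bootstrap replicate, resample residuals with replacement,
   add them to the fitted values, and refit, collecting the coefficient
   vector;
3. rank coefficient vectors by (approximate) Tukey halfspace depth and
   keep the deepest 95%;
4. numerically maximize each retained surface over the sampled box;
   the convex hull of those maxima is the confidence region and their
   centroid is the point estimate of the peak.

Thin-plate splines (with the smoothing parameter chosen by generalized
cross-validation) are provided for visualizing the same surfaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

from .data_model import DataError

__all__ = [
    "QuadraticSurface",
    "PeakRegion",
    "TpsSurface",
    "fit_quadratic_surface",
    "surface_maximum",
    "bootstrap_peak_region",
    "tukey_depth",
    "tukey_depth_approx",
    "tukey_depth_exact_2d",
    "tps_fit",
    "surface_grid",
]


# ---------------------------------------------------------------------------
# quadratic response surface


@dataclass
class QuadraticSurface:
    """Second-order response surface y = b0 + b'x + x'Ax (A symmetric)."""

    intercept: float
    linear: np.ndarray
    curvature: np.ndarray
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        if not np.allclose(self.curvature, self.curvature.T, atol=1e-10):
            raise DataError("curvature matrix must be symmetric")

    @property
    def d(self) -> int:
        return self.linear.shape[0]

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        quad = np.einsum("ni,ij,nj->n", X, self.curvature, X)
        return self.intercept + X @ self.linear + quad


def _quad_design(X: np.ndarray) -> np.ndarray:
    n, d = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, j] for j in range(d))
    cols.extend(X[:, j] ** 2 for j in range(d))
    for i in range(d):
        for j in range(i + 1, d):
            cols.append(X[:, i] * X[:, j])
    return np.column_stack(cols)


def _coef_to_surface(coef: np.ndarray, d: int) -> QuadraticSurface:
    A = np.zeros((d, d))
    A[np.diag_indices(d)] = coef[1 + d : 1 + 2 * d]
    k = 1 + 2 * d
    for i in range(d):
        for j in range(i + 1, d):
            A[i, j] = A[j, i] = coef[k] / 2.0  # split the cross term
            k += 1
    return QuadraticSurface(float(coef[0]), coef[1 : 1 + d], A)


def fit_quadratic_surface(X: np.ndarray, y: np.ndarray) -> QuadraticSurface:
    """OLS fit of a full quadratic polynomial, storing residuals."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    q = (d + 1) * (d + 2) // 2
    if n <= q:
        raise DataError(f"need n > {q} points to fit a quadratic in {d} variables")
    D = _quad_design(X)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise DataError("quadratic design is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    surf = _coef_to_surface(coef, d)
    surf.fitted = D @ coef
    surf.residuals = y - surf.fitted
    return surf


# ---------------------------------------------------------------------------
# box-constrained maximization


def _max_on_box_2d(surface: QuadraticSurface, bounds: np.ndarray
                   ) -> np.ndarray:
    """Exact maximizer of a 2-D quadratic over a rectangle.

    Enumerates the interior stationary point, the stationary point of
    each edge restriction, and the four corners.
    """
    b, A = surface.linear, surface.curvature
    (lo1, hi1), (lo2, hi2) = bounds
    candidates = [np.array(c) for c in
                  itertools.product((lo1, hi1), (lo2, hi2))]
    if abs(np.linalg.det(2 * A)) > 1e-14:
        x0 = np.linalg.solve(2 * A, -b)
        if lo1 <= x0[0] <= hi1 and lo2 <= x0[1] <= hi2:
            candidates.append(x0)
    # edge restrictions: fix one coordinate, 1-D quadratic in the other
    for j_fix, vals in ((0, (lo1, hi1)), (1, (lo2, hi2))):
        j_free = 1 - j_fix
        for v in vals:
            a2 = A[j_free, j_free]
            a1 = b[j_free] + 2 * A[j_free, j_fix] * v
            if abs(a2) > 1e-14:
                t = -a1 / (2 * a2)
                lo, hi = bounds[j_free]
                if lo <= t <= hi:
                    x = np.empty(2)
                    x[j_fix] = v
                    x[j_free] = t
                    candidates.append(x)
    vals = surface.evaluate(np.vstack(candidates))
    return candidates[int(np.argmax(vals))]


def surface_maximum(
    surface: QuadraticSurface,
    bounds,
    return_boundary_flag: bool = False,
):
    """Global maximizer of the surface over an axis-aligned box.

    If the curvature is negative definite and the unconstrained
    stationary point -A^{-1}b/2 lies inside the box, that point is
    returned directly. Otherwise the maximum is found exactly on the
    box (d = 2) or by deterministic multi-start local optimization
    (d > 2). Maxima on the box boundary are flagged: they indicate the
    fitted surface peaks outside the sampled phenotypic range.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (surface.d, 2) or not np.isfinite(bounds).all():
        raise DataError("bounds must be a finite (d, 2) interval box")
    b, A = surface.linear, surface.curvature
    eig = np.linalg.eigvalsh(A)
    x_star = None
    if eig.max() < 0:
        x0 = np.linalg.solve(2 * A, -b)
        if np.all(x0 >= bounds[:, 0]) and np.all(x0 <= bounds[:, 1]):
            x_star = x0
    if x_star is None:
        if surface.d == 2:
            x_star = _max_on_box_2d(surface, bounds)
        else:
            x_star = _max_multistart(surface, bounds)
    on_boundary = bool(
        np.any(np.isclose(x_star, bounds[:, 0], atol=1e-9))
        or np.any(np.isclose(x_star, bounds[:, 1], atol=1e-9))
    )
    if return_boundary_flag:
        return x_star, on_boundary
    return x_star


def _max_multistart(surface: QuadraticSurface, bounds: np.ndarray
                    ) -> np.ndarray:
    starts = itertools.product(*(np.linspace(lo, hi, 3) for lo, hi in bounds))
    best_x, best_v = None, -np.inf

    def neg(x: np.ndarray):
        return -(surface.intercept + surface.linear @ x
                 + x @ surface.curvature @ x)

    def neg_grad(x: np.ndarray):
        return -(surface.linear + 2 * surface.curvature @ x)

    for s in starts:
        res = minimize(neg, np.array(s), jac=neg_grad, method="L-BFGS-B",
                       bounds=bounds)
        if -res.fun > best_v:
            best_v, best_x = -res.fun, res.x
    return best_x


# ---------------------------------------------------------------------------
# Tukey halfspace depth


def tukey_depth(cloud: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Halfspace depth of every cloud point over the given directions.

    depth(q) = min over directions u of the fraction of cloud points p
    (q itself included) with u.p >= u.q. With finitely many directions
    this is an upper bound on the exact halfspace depth, non-increasing
    as directions are added.
    """
    cloud = np.asarray(cloud, dtype=float)
    m = cloud.shape[0]
    proj = cloud @ directions  # (m, n_dir)
    # ordinal rank within each direction: rank r (0-based, ascending)
    # means m - r points project at or above this one (ties broken by
    # sort order; exact for tie-free clouds)
    order = np.argsort(proj, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(m)
    for k in range(proj.shape[1]):
        ranks[order[:, k], k] = rows
    counts_ge = m - ranks
    return counts_ge.min(axis=1) / m


def tukey_depth_approx(
    cloud: np.ndarray, n_directions: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Random-projection approximation of Tukey depth (seeded).

    Exact halfspace depth is exponential in dimension; projecting onto
    random unit directions gives a cheap upper-bound approximation that
    is adequate for ranking bootstrap coefficient vectors by centrality.
    """
    cloud = np.asarray(cloud, dtype=float)
    if cloud.shape[0] < 2:
        raise DataError("depth needs at least 2 points")
    if n_directions < 100:
        raise DataError("use at least 100 directions")
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((cloud.shape[1], n_directions))
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    return tukey_depth(cloud, U)


def tukey_depth_exact_2d(cloud: np.ndarray) -> np.ndarray:
    """Exact halfspace depth in 2-D by angular sweep (test oracle).

    For each point the count of points in a closed halfplane through it
    changes only when the direction crosses the perpendicular of some
    displacement vector, so the minimum is attained at one of those
    critical angles (evaluated with a small nudge to either side).
    """
    cloud = np.asarray(cloud, dtype=float)
    m, d = cloud.shape
    if d != 2:
        raise DataError("exact sweep is 2-D only")
    depths = np.empty(m)
    eps = 1e-9
    for i in range(m):
        v = cloud - cloud[i]
        nonzero = np.linalg.norm(v, axis=1) > 0
        n_coincident = int((~nonzero).sum())  # includes the point itself
        vv = v[nonzero]
        if vv.shape[0] == 0:
            depths[i] = 1.0
            continue
        ang = np.arctan2(vv[:, 1], vv[:, 0])
        cand = np.concatenate([ang + np.pi / 2, ang - np.pi / 2])
        cand = np.concatenate([cand - eps, cand, cand + eps])
        u = np.column_stack([np.cos(cand), np.sin(cand)])
        counts = (vv @ u.T >= -1e-12).sum(axis=0)
        depths[i] = (counts.min() + n_coincident) / m
    return depths


# ---------------------------------------------------------------------------
# bootstrap confidence region


@dataclass
class PeakRegion:
    """Bootstrap confidence region for the fitness-surface maximum."""

    maxima_cloud: np.ndarray
    hull_vertices: np.ndarray
    centroid: np.ndarray
    retain: float
    bounds: np.ndarray
    boundary_fraction: float
    nonconcave_fraction: float
    degenerate: bool = False
    coefficient_cloud: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_retained(self) -> int:
        return int(self.maxima_cloud.shape[0])

    def contains(self, point) -> bool:
        """Is the point inside (or on) the convex hull of the maxima?"""
        point = np.asarray(point, dtype=float)
        if self.degenerate:
            return bool(np.allclose(point, self.centroid, atol=1e-9))
        verts = self.hull_vertices
        # ordered polygon: inside iff on the same side of every edge
        nv = verts.shape[0]
        sign = 0.0
        for k in range(nv):
            a, bpt = verts[k], verts[(k + 1) % nv]
            cross = (bpt[0] - a[0]) * (point[1] - a[1]) - (
                bpt[1] - a[1]) * (point[0] - a[0])
            if abs(cross) < 1e-12:
                continue
            if sign == 0.0:
                sign = np.sign(cross)
            elif np.sign(cross) != sign:
                return False
        return True


def bootstrap_peak_region(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    retain: float = 0.95,
    n_directions: int = 10_000,
    seed: int = 0,
    bounds=None,
) -> PeakRegion:
    """Residual-bootstrap 95% confidence region for the surface maximum.

    Depth filtering is applied to the bootstrap coefficient vectors
    (not to the maxima): the deepest ``retain`` fraction define the
    retained surfaces, and the region is the convex hull of their
    box-constrained maxima. Non-concave refits are kept (their
    constrained maxima sit on the box boundary) and counted in the
    diagnostics. The default search box is the axis-aligned range of
    the observed scores, since a stabilizing-selection claim requires
    the peak to lie within the sampled phenotypic space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if B < 100:
        raise DataError("B must be at least 100")
    if not (0.5 < retain < 1.0):
        raise DataError("retain must lie in (0.5, 1)")
    n, d = X.shape
    if bounds is None:
        bounds = np.column_stack([X.min(axis=0), X.max(axis=0)])
    bounds = np.asarray(bounds, dtype=float)
    if np.any(bounds[:, 0] > X.min(axis=0)) or np.any(bounds[:, 1] < X.max(axis=0)):
        raise DataError("bounds must cover the observed score range")

    surf = fit_quadratic_surface(X, y)
    D = _quad_design(X)
    pinv = np.linalg.pinv(D)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n, B))
    Ystar = surf.fitted[:, None] + surf.residuals[idx]
    coefs = (pinv @ Ystar).T  # (B, q)

    spread = coefs.max(axis=0) - coefs.min(axis=0)
    degenerate_cloud = bool(np.all(spread < 1e-12))

    n_keep = int(round(retain * B))
    if degenerate_cloud:
        keep = np.arange(n_keep)
    else:
        depth = tukey_depth_approx(coefs, n_directions=n_directions, seed=seed)
        keep = np.argsort(-depth, kind="stable")[:n_keep]

    maxima = np.empty((n_keep, d))
    boundary = 0
    nonconcave = 0
    for out_row, bidx in enumerate(keep):
        s = _coef_to_surface(coefs[bidx], d)
        if np.linalg.eigvalsh(s.curvature).max() >= 0:
            nonconcave += 1
        x_star, on_bd = surface_maximum(s, bounds, return_boundary_flag=True)
        boundary += on_bd
        maxima[out_row] = x_star

    centroid = maxima.mean(axis=0)
    degenerate = degenerate_cloud or bool(
        np.all(maxima.max(axis=0) - maxima.min(axis=0) < 1e-10)
    )
    if degenerate:
        hull_vertices = maxima[:1].copy()
    else:
        try:
            hull = ConvexHull(maxima)
            hull_vertices = maxima[hull.vertices]
        except QhullError:
            degenerate = True
            hull_vertices = np.unique(maxima, axis=0)

    return PeakRegion(
        maxima_cloud=maxima,
        hull_vertices=hull_vertices,
        centroid=centroid,
        retain=retain,
        bounds=bounds,
        boundary_fraction=boundary / n_keep,
        nonconcave_fraction=nonconcave / n_keep,
        degenerate=degenerate,
        coefficient_cloud=coefs,
    )


# ---------------------------------------------------------------------------
# thin-plate splines


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass
class TpsSurface:
    """Thin-plate spline surface over 2-D sites.

    At smoothing 0 the spline interpolates the data; as smoothing grows
    it shrinks toward the least-squares affine fit. ``gcv_score`` is
    stored when the smoothing parameter was selected by generalized
    cross-validation.
    """

    knots: np.ndarray
    coef_kernel: np.ndarray
    coef_affine: np.ndarray
    smoothing: float
    gcv_score: float | None = None

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        r = np.linalg.norm(X[:, None, :] - self.knots[None, :, :], axis=2)
        P = np.column_stack([np.ones(X.shape[0]), X])
        return _tps_kernel(r) @ self.coef_kernel + P @ self.coef_affine


def _tps_solve(K: np.ndarray, P: np.ndarray, y: np.ndarray, lam: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the penalized TPS system; returns (c, d, influence diag trace info)."""
    n = K.shape[0]
    top = np.hstack([K + n * lam * np.eye(n), P])
    bottom = np.hstack([P.T, np.zeros((3, 3))])
    sys = np.vstack([top, bottom])
    rhs = np.concatenate([y, np.zeros(3)])
    sol = np.linalg.solve(sys, rhs)
    return sol[:n], sol[n:], sys


def _tps_gcv(K: np.ndarray, P: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Generalized cross-validation score n*RSS / tr(I - A)^2."""
    n = K.shape[0]
    top = np.hstack([K + n * lam * np.eye(n), P])
    bottom = np.hstack([P.T, np.zeros((3, 3))])
    sys = np.vstack([top, bottom])
    rhs = np.vstack([np.eye(n), np.zeros((3, n))])
    sol = np.linalg.solve(sys, rhs)
    A = K @ sol[:n] + P @ sol[n:]
    fitted = A @ y
    rss = float(np.sum((y - fitted) ** 2))
    denom = float(np.trace(np.eye(n) - A)) ** 2
    if denom <= 0:
        return np.inf
    return n * rss / denom


def tps_fit(
    X: np.ndarray,
    y: np.ndarray,
    smoothing: float | str = "gcv",
    gcv_grid: np.ndarray | None = None,
) -> TpsSurface:
    """Fit a thin-plate spline to scattered 2-D data.

    ``smoothing`` is either a nonnegative penalty or ``"gcv"``, in
    which case the penalty minimizing the generalized cross-validation
    score over a log-spaced grid is used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if d != 2:
        raise DataError("thin-plate surface fitting is 2-D")
    if n < 4:
        raise DataError("need at least 4 sites")
    r = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    has_dups = bool(np.any(r[np.triu_indices(n, 1)] == 0))
    K = _tps_kernel(r)
    P = np.column_stack([np.ones(n), X])

    gcv_score = None
    if smoothing == "gcv":
        if gcv_grid is None:
            gcv_grid = np.logspace(-8, 2, 41)
        scores = np.array([_tps_gcv(K, P, y, lam) for lam in gcv_grid])
        best = int(np.argmin(scores))
        lam = float(gcv_grid[best])
        gcv_score = float(scores[best])
    else:
        lam = float(smoothing)
        if lam < 0:
            raise DataError("smoothing must be nonnegative")
    if lam == 0 and has_dups:
        raise DataError("duplicate sites: interpolation (smoothing 0) undefined")

    c, dcoef, _ = _tps_solve(K, P, y, lam)
    return TpsSurface(knots=X.copy(), coef_kernel=c, coef_affine=dcoef,
                      smoothing=lam, gcv_score=gcv_score)


def surface_grid(surface, resolution: int, bounds) -> np.ndarray:
    """Row-major (x1, x2, fitness) grid for contour export.

    Works for any surface exposing ``evaluate``; returns an array of
    shape (resolution**2, 3).
    """
    if resolution < 2:
        raise DataError("resolution must be at least 2")
    bounds = np.asarray(bounds, dtype=float)
    g1 = np.linspace(bounds[0, 0], bounds[0, 1], resolution)
    g2 = np.linspace(bounds[1, 0], bounds[1, 1], resolution)
    XX, YY = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    vals = surface.evaluate(pts)
    return np.column_stack([pts, vals])
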