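"""Two-dimensional thin-plate spline (TPS) interpolation.

The TPS is the unique map that carries a set of source landmarks exactly onto
a set of target landmarks while minimizing the integral of squared second
derivatives of the mapping ("bending energy").  It decomposes into an affine
part and a non-affine part spanned by radially symmetric kernel functions
centered at the source landmarks.  This module provides the kernel, the
fitting and evaluation routines, the closed-form bending-energy quadratic
form needed by the sliding-semilandmark algorithm, deformation-grid geometry
for visualization, and a Newton inverse used when rendering synthetic images.

Conventions
-----------
* Kernel ``U(r) = r^2 ln r`` with the natural logarithm and ``U(0) = 0``
  (the limit value).  Using ``log2`` instead would rescale bending energies
  by a constant factor; the natural-log convention is fixed here so that all
  reported energies are comparable.
* Bending energy is summed over the two output coordinates.
* Points are ``(k, 2)`` float arrays, ``x`` first, ``y`` second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist


class DegenerateConfigurationError(ValueError):
    """Raised when a landmark configuration cannot support a TPS fit.

    This happens for duplicated landmarks, (near-)collinear configurations,
    or any other source of an ill-conditioned TPS system.
    """


#: Default guard below which inter-point distances are treated as zero.
DEFAULT_EPSILON = 1e-12

#: Condition-number cutoff above which the TPS system is declared degenerate.
COND_MAX = 1e12


def _as_points(points, name: str = "points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be a (k, 2) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def validate_point_set(points, *, min_points: int = 3,
                       epsilon: float = DEFAULT_EPSILON,
                       name: str = "points") -> np.ndarray:
    """Validate a point set for TPS fitting.

    Checks shape, finiteness, minimum count, duplicate points (minimum
    pairwise distance above ``epsilon``) and collinearity.
    """
    pts = _as_points(points, name)
    k = pts.shape[0]
    if k < min_points:
        raise ValueError(f"{name} needs at least {min_points} points, got {k}")
    d = pdist(pts)
    if d.size and d.min() <= epsilon:
        i, j = _closest_pair(pts)
        raise DegenerateConfigurationError(
            f"{name} has (near-)duplicate points {i} and {j} "
            f"(distance {d.min():.3e} <= epsilon {epsilon:.3e})"
        )
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= epsilon * max(1.0, s[0]):
        raise DegenerateConfigurationError(f"{name}: all points are collinear")
    return pts


def _closest_pair(pts: np.ndarray) -> tuple[int, int]:
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return int(min(i, j)), int(max(i, j))


def tps_kernel(r, epsilon: float = DEFAULT_EPSILON):
    """TPS radial kernel ``U(r) = r^2 ln r`` with ``U(0) = 0``.

    ``epsilon`` guards the logarithm: distances at or below it are mapped
    to zero, the limit of ``r^2 ln r`` as ``r -> 0``.
    """
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    mask = r > epsilon
    rm = r[mask]
    out[mask] = rm * rm * np.log(rm)
    return out


@dataclass(frozen=True)
class TPSTransform:
    """A fitted thin-plate-spline map between two 2-D point sets.

    Attributes
    ----------
    source : (k, 2) ndarray
        Landmarks the kernel functions are centered on.
    affine : (3, 2) ndarray
        Affine coefficients per output coordinate: row 0 the constant term,
        rows 1-2 the linear terms in x and y.
    weights : (k, 2) ndarray
        Non-affine kernel weights per output coordinate.  They satisfy the
        side conditions ``sum(w) = 0`` and ``w . source = 0`` per coordinate.
    bending_energy : float
        ``sum_c w_c^T K w_c`` over the two output coordinates; zero iff the
        map is affine.
    kernel_epsilon : float
        Guard used when evaluating the kernel near ``r = 0``.
    """

    source: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float
    kernel_epsilon: float = DEFAULT_EPSILON
    _target: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def k(self) -> int:
        return self.source.shape[0]

    def __call__(self, points) -> np.ndarray:
        return tps_apply(self, points)


def _tps_design(source: np.ndarray, points: np.ndarray,
                epsilon: float) -> np.ndarray:
    """Rows [U(|p - s_1|), ..., U(|p - s_k|), 1, x, y] for each query point."""
    k = source.shape[0]
    m = points.shape[0]
    design = np.empty((m, k + 3))
    design[:, :k] = tps_kernel(cdist(points, source), epsilon)
    design[:, k] = 1.0
    design[:, k + 1:] = points
    return design


def _tps_system(source: np.ndarray, epsilon: float,
                ridge: float) -> np.ndarray:
    """Assemble the (k+3) x (k+3) TPS interpolation matrix L = [[K, P], [P^T, 0]]."""
    k = source.shape[0]
    K = tps_kernel(cdist(source, source), epsilon)
    if ridge:
        K = K + ridge * np.eye(k)
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k] = 1.0
    L[:k, k + 1:] = source
    L[k, :k] = 1.0
    L[k + 1:, :k] = source.T
    return L


def tps_fit(source, target, *, ridge: float = 0.0,
            epsilon: float = DEFAULT_EPSILON,
            cond_max: float = COND_MAX) -> TPSTransform:
    """Fit the thin-plate spline carrying ``source`` exactly onto ``target``.

    Parameters
    ----------
    source, target : (k, 2) array_like
        Corresponding landmarks, ``k >= 3``, source non-degenerate.
    ridge : float
        Optional regularization added to the kernel diagonal for
        near-duplicate landmarks (default 0: exact interpolation).
    epsilon : float
        Kernel guard and degeneracy threshold for distances.
    cond_max : float
        Condition-number cutoff on the TPS system before declaring the
        configuration degenerate.

    Raises
    ------
    DegenerateConfigurationError
        For duplicate or collinear source landmarks, or an ill-conditioned
        system.
    ValueError
        If the point counts differ or inputs are malformed.
    """
    src = validate_point_set(source, epsilon=epsilon, name="source")
    tgt = _as_points(target, "target")
    if tgt.shape[0] != src.shape[0]:
        raise ValueError(
            f"source has {src.shape[0]} points but target has {tgt.shape[0]}"
        )
    k = src.shape[0]
    # Solve in a normalized source frame (centered, RMS-scaled): the TPS
    # interpolant is equivariant under similarity transforms of its domain,
    # and the normalized system has a scale-invariant condition number.
    mu = src.mean(axis=0)
    sigma = float(np.sqrt(np.mean(np.sum((src - mu) ** 2, axis=1))))
    shat = (src - mu) / sigma
    L = _tps_system(shat, epsilon, ridge)
    cond = np.linalg.cond(L)
    if not np.isfinite(cond) or cond > cond_max:
        raise DegenerateConfigurationError(
            f"TPS system is ill-conditioned (cond={cond:.3e} > {cond_max:.3e}); "
            "check for duplicated or collinear landmarks"
        )
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    sol = np.linalg.solve(L, rhs)
    w_hat = sol[:k]
    a_hat = sol[k:]
    K = L[:k, :k] - (ridge * np.eye(k) if ridge else 0.0)
    be = float(np.einsum("kc,kl,lc->", w_hat, K, w_hat)) / sigma ** 2
    # Clamp the tiny negative values that exact-arithmetic zero can round to.
    be = max(be, 0.0)
    # Convert coefficients to the raw-coordinate kernel representation:
    # U(r/sigma) = (r^2 ln r - r^2 ln sigma) / sigma^2, and the side
    # conditions turn the ln(sigma) term into a constant per coordinate.
    weights = w_hat / sigma ** 2
    affine = np.empty((3, 2))
    const_corr = (np.log(sigma) / sigma ** 2) * (
        np.sum(src ** 2, axis=1) @ w_hat)
    affine[0] = a_hat[0] - (a_hat[1:].T @ mu) / sigma - const_corr
    affine[1:] = a_hat[1:] / sigma
    return TPSTransform(source=src, affine=affine, weights=weights,
                        bending_energy=be, kernel_epsilon=epsilon,
                        _target=tgt)


def tps_apply(transform: TPSTransform, points) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary points.

    Returns an array with the same count and order as ``points``.
    """
    pts = _as_points(points)
    design = _tps_design(transform.source, pts, transform.kernel_epsilon)
    coef = np.vstack([transform.weights, transform.affine])
    return design @ coef


def bending_energy_matrix(reference, *, ridge: float = 0.0,
                          epsilon: float = DEFAULT_EPSILON,
                          cond_max: float = COND_MAX) -> np.ndarray:
    """Closed-form bending-energy quadratic form of a reference configuration.

    Returns the symmetric positive semi-definite ``(k, k)`` matrix ``B`` such
    that for any target configuration ``T`` (per coordinate column ``t``),
    ``t^T B t`` equals the bending energy of the TPS from ``reference`` to
    ``T`` in that coordinate.  ``B`` annihilates the affine subspace
    (constant, x, y), so affine deformations cost zero energy.

    ``B`` is the upper-left ``k x k`` block of the inverse of the bordered
    TPS system matrix.
    """
    ref = validate_point_set(reference, epsilon=epsilon, name="reference")
    k = ref.shape[0]
    mu = ref.mean(axis=0)
    sigma = float(np.sqrt(np.mean(np.sum((ref - mu) ** 2, axis=1))))
    L = _tps_system((ref - mu) / sigma, epsilon, ridge)
    cond = np.linalg.cond(L)
    if not np.isfinite(cond) or cond > cond_max:
        raise DegenerateConfigurationError(
            f"TPS system is ill-conditioned (cond={cond:.3e} > {cond_max:.3e})"
        )
    B = np.linalg.inv(L)[:k, :k] / sigma ** 2
    return (B + B.T) / 2.0


def bending_energy(reference_matrix: np.ndarray, target) -> float:
    """Quadratic-form bending energy of ``target`` against a reference matrix.

    ``reference_matrix`` is the output of :func:`bending_energy_matrix`; the
    energy is summed over the two coordinates.
    """
    tgt = _as_points(target, "target")
    val = float(np.einsum("kc,kl,lc->", tgt, reference_matrix, tgt))
    return max(val, 0.0)


def deformation_grid(from_shape, to_shape, grid_rows: int = 20,
                     grid_cols: int = 20, margin: float = 0.05,
                     **fit_kwargs):
    """Deformed regular grid visualizing the TPS map between two shapes.

    A regular ``grid_rows x grid_cols`` grid covering the bounding box of
    ``from_shape`` (expanded by ``margin``, a fraction of each side) is mapped
    through the TPS fitted from ``from_shape`` to ``to_shape``.

    Returns
    -------
    (row_polylines, col_polylines) : tuple of lists of (m, 2) ndarray
        Images of the horizontal and vertical grid lines, ready to plot.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("grid_rows and grid_cols must be >= 2")
    frm = _as_points(from_shape, "from_shape")
    transform = tps_fit(frm, to_shape, **fit_kwargs)
    lo = frm.min(axis=0)
    hi = frm.max(axis=0)
    pad = margin * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_cols)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_rows)
    gx, gy = np.meshgrid(xs, ys)
    vertices = np.column_stack([gx.ravel(), gy.ravel()])
    warped = tps_apply(transform, vertices).reshape(grid_rows, grid_cols, 2)
    row_polylines = [warped[i] for i in range(grid_rows)]
    col_polylines = [warped[:, j] for j in range(grid_cols)]
    return row_polylines, col_polylines


def tps_jacobian(transform: TPSTransform, points) -> np.ndarray:
    """Analytic Jacobian of a TPS map at each query point.

    Returns an ``(m, 2, 2)`` array ``J[i, a, b] = d out_a / d in_b``.  The
    kernel gradient is ``dU/dp = (2 ln r + 1)(p - s)`` with limit 0 at
    ``r = 0``.
    """
    pts = _as_points(points)
    src = transform.source
    eps = transform.kernel_epsilon
    diff = pts[:, None, :] - src[None, :, :]          # (m, k, 2)
    r = np.linalg.norm(diff, axis=2)                  # (m, k)
    factor = np.zeros_like(r)
    mask = r > eps
    factor[mask] = 2.0 * np.log(r[mask]) + 1.0
    # grad_b U(|p - s_j|) = factor * diff_b ; J_ab = A_ab + sum_j w_jc ...
    grad = factor[:, :, None] * diff                  # (m, k, 2) d/d in_b
    J = np.einsum("jc,mjb->mcb", transform.weights, grad)
    J += transform.affine[1:].T[None, :, :]
    return J


def tps_inverse(transform: TPSTransform, points, *, max_iter: int = 30,
                tol: float = 1e-10) -> np.ndarray:
    """Numerically invert a TPS map at the given points (vectorized Newton).

    Solves ``transform(x) = p`` for each query ``p``, starting from ``p``
    itself.  Intended for modest, orientation-preserving deformations such as
    those used when rendering synthetic specimens; not guaranteed for folded
    maps.
    """
    targets = _as_points(points)
    x = targets.copy()
    for _ in range(max_iter):
        resid = tps_apply(transform, x) - targets
        err = np.abs(resid).max()
        if err < tol:
            break
        J = tps_jacobian(transform, x)
        step = np.linalg.solve(J, resid[:, :, None])[:, :, 0]
        x -= step
    return x
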