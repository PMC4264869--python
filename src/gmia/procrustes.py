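"""Procrustes superimposition of landmark configurations.

Generalized Procrustes Analysis (GPA) removes position, scale, and
orientation from a sample of landmark configurations: each configuration is
translated so its centroid sits at the origin, scaled to unit centroid size,
and iteratively rotated to minimize the summed squared distances to the
evolving sample mean.  The resulting *Procrustes shape coordinates*
parameterize shape alone, and Euclidean distances between them approximate
the Procrustes distance.

Rotations exclude reflections (specimens are imaged in a standardized
orientation).  The global rotation gauge left free by GPA is pinned by
aligning the principal axes of the final mean shape with the coordinate
axes, which makes outputs reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


def centroid_size(points) -> float:
    """Centroid size: root summed squared distances of points from centroid.

    Raises
    ------
    ValueError
        If all points coincide (zero size) or coordinates are malformed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (k, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt(np.sum(centered ** 2)))
    if size == 0.0:
        raise ValueError("all points coincide: centroid size is zero")
    return size


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||a @ R - b||_F.

    Both configurations must already be centered.
    """
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def ordinary_procrustes(moving, fixed, *, scale: bool = True):
    """Closed-form superimposition of one configuration onto another.

    Translates, optionally scales, and rotates (no reflection) ``moving`` to
    best fit ``fixed`` in the least-squares sense.

    Returns
    -------
    aligned : (k, 2) ndarray
        The transformed ``moving`` configuration.
    params : dict
        ``rotation`` (2x2), ``scale`` (float), ``translation`` (2,) such that
        ``aligned = scale * (moving - moving_centroid) @ rotation + translation``.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError("configurations must have matching shapes")
    mc = mov.mean(axis=0)
    fc = fix.mean(axis=0)
    a = mov - mc
    b = fix - fc
    R = optimal_rotation(a, b)
    if scale:
        s = float(np.trace(R.T @ a.T @ b) / np.sum(a ** 2))
    else:
        s = 1.0
    aligned = s * a @ R + fc
    return aligned, {"rotation": R, "scale": s, "translation": fc}


def procrustes_distance(a, b) -> float:
    """Euclidean distance between two sets of Procrustes shape coordinates.

    Both configurations must already be aligned in a common GPA frame and
    have the same landmark count.
    """
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("configurations must have matching landmark counts")
    return float(np.sqrt(np.sum((pa - pb) ** 2)))


@dataclass
class ProcrustesResult:
    """Output of a Generalized Procrustes Analysis.

    ``shapes`` are the aligned configurations (centroid at origin, unit
    centroid size), ``mean_shape`` their coordinate-wise average,
    ``centroid_sizes`` the original sizes removed by the scaling step.
    """

    shapes: np.ndarray          # (n, k, 2)
    mean_shape: np.ndarray      # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool

    @property
    def flat(self) -> np.ndarray:
        """Shape coordinates flattened to an (n, 2k) matrix (x0 y0 x1 y1 ...)."""
        n = self.shapes.shape[0]
        return self.shapes.reshape(n, -1)


def _principal_axis_rotation(mean: np.ndarray) -> np.ndarray:
    """Deterministic det-+1 rotation sending the mean's principal axes to x/y.

    The sign of the first axis is pinned so that the landmark with the
    largest absolute score along it projects positively; the second axis sign
    follows from det = +1.
    """
    cov = mean.T @ mean
    _, vecs = np.linalg.eigh(cov)
    v1 = vecs[:, 1]  # leading axis (eigh sorts ascending)
    proj = mean @ v1
    pin = int(np.argmax(np.abs(proj)))
    if proj[pin] < 0:
        v1 = -v1
    v2 = np.array([-v1[1], v1[0]])  # det(+1) completion
    R = np.column_stack([v1, v2])
    return R


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Generalized Procrustes Analysis as a fit/transform estimator.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the change of the mean shape between
        iterations (Frobenius norm).
    max_iter : int
        Maximum number of mean/rotation refinement iterations.  Hitting the
        cap flags ``converged_ = False`` rather than raising.
    principal_axes : bool
        Pin the global rotation gauge by aligning the final mean's principal
        axes with the coordinate axes (default True).

    Attributes
    ----------
    mean_shape_ : (k, 2) ndarray
    shapes_ : (n, k, 2) ndarray of aligned training configurations
    centroid_sizes_ : (n,) ndarray
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 principal_axes: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.principal_axes = principal_axes

    @staticmethod
    def _stack(X, min_n: int = 2) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) array of configurations")
        if arr.shape[0] < min_n:
            raise ValueError(f"need at least {min_n} configurations")
        if not np.all(np.isfinite(arr)):
            raise ValueError("configurations contain non-finite coordinates")
        return arr

    def fit(self, X, y=None):
        arr = self._stack(X)
        n = arr.shape[0]
        sizes = np.array([centroid_size(c) for c in arr])
        shapes = np.array([(c - c.mean(axis=0)) / s
                           for c, s in zip(arr, sizes)])
        mean = shapes[0].copy()
        mean /= np.sqrt(np.sum(mean ** 2))
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                shapes[i] = shapes[i] @ optimal_rotation(shapes[i], mean)
            new_mean = shapes.mean(axis=0)
            new_mean -= new_mean.mean(axis=0)
            new_mean /= np.sqrt(np.sum(new_mean ** 2))
            delta = float(np.linalg.norm(new_mean - mean))
            mean = new_mean
            if delta < self.tol:
                converged = True
                break
        if self.principal_axes:
            R = _principal_axis_rotation(mean)
            mean = mean @ R
            shapes = shapes @ R
        self.mean_shape_ = shapes.mean(axis=0)
        self.shapes_ = shapes
        self.centroid_sizes_ = sizes
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def transform(self, X) -> np.ndarray:
        """Align new configurations to the fitted mean shape."""
        arr = self._stack(X, min_n=1)
        out = np.empty_like(arr)
        for i, cfg in enumerate(arr):
            centered = cfg - cfg.mean(axis=0)
            centered /= centroid_size(cfg)
            out[i] = centered @ optimal_rotation(centered, self.mean_shape_)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.shapes_

    def result_(self) -> ProcrustesResult:
        return ProcrustesResult(
            shapes=self.shapes_, mean_shape=self.mean_shape_,
            centroid_sizes=self.centroid_sizes_, iterations=self.n_iter_,
            converged=self.converged_,
        )


def gpa(configs, tol: float = 1e-10, max_iter: int = 100,
        principal_axes: bool = True) -> ProcrustesResult:
    """Generalized Procrustes Analysis of a sample of configurations.

    Thin functional wrapper over :class:`GeneralizedProcrustes`.  ``configs``
    may be an (n, k, 2) array, a list of (k, 2) arrays, or a list of
    :class:`~gmia.landmarks.LandmarkConfiguration`.
    """
    arr = _configs_to_array(configs)
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter,
                                principal_axes=principal_axes).fit(arr)
    return est.result_()


def _configs_to_array(configs) -> np.ndarray:
    items = []
    for c in configs:
        items.append(c.points if hasattr(c, "points") else np.asarray(c, float))
    ks = {p.shape for p in items}
    if len(ks) != 1:
        raise ValueError(f"configurations disagree in landmark count: {ks}")
    return np.asarray(items, dtype=float)
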