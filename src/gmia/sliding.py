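"""Sliding semilandmarks along curve tangents by bending-energy minimization.

Semilandmarks carry no anatomical point homology along their curve, so their
along-curve positions are estimated: each specimen's semilandmarks are
iteratively displaced along local tangent directions so as to minimize the
bending energy of the thin-plate spline between the specimen and a fixed
reference (average) configuration.  The tangent at a semilandmark is the
vector connecting its two along-curve neighbors; at the open ends of a curve
it is the vector to the single neighbor.  All curves here are open, and the
reference is computed once and held fixed while every specimen is slid
against it — the variant that guarantees convergence to a non-degenerate
mean when curves are not anchored by anatomical endpoints.

Because the bending-energy objective is a quadratic form in the landmark
coordinates and the tangent constraint is linear, each iteration solves the
*exact* constrained minimizer for all semilandmarks of a specimen jointly
(one small linear system), rather than sliding point by point.  Semilandmarks
stay on their tangent lines; the digitized curve is treated as locally
linear, so no re-projection step follows.

Before sliding, each configuration is superimposed onto the reference by
ordinary Procrustes (translation, scale, rotation); slid coordinates are
mapped back so outputs live in the specimen's original digitizing frame.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkConfiguration
from .procrustes import gpa, ordinary_procrustes
from .tps import bending_energy, bending_energy_matrix


class TangentUndefinedError(ValueError):
    """A semilandmark's along-curve neighbors coincide, leaving no tangent."""


def _tangents(config: LandmarkConfiguration, points: np.ndarray,
              semis=None) -> np.ndarray:
    """Unit tangent per sliding semilandmark (rows follow ``semis`` order)."""
    if semis is None:
        semis = config.semilandmark_indices
    tangents = np.zeros((len(semis), 2))
    for row, idx in enumerate(semis):
        prev, nxt = config.curve_neighbors(int(idx))
        a = points[prev] if prev is not None else points[idx]
        b = points[nxt] if nxt is not None else points[idx]
        vec = b - a
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            raise TangentUndefinedError(
                f"specimen '{config.specimen_id}': tangent undefined at "
                f"point {idx} (coincident neighbors)")
        tangents[row] = vec / norm
    return tangents


def _slide_once(points: np.ndarray, semis: np.ndarray,
                tangents: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact minimizer of the bending-energy form over tangent displacements.

    Positions become ``p_j + t_j * u_j`` for semilandmarks ``j``; anatomical
    landmarks stay fixed.  With ``B`` the reference bending-energy matrix the
    objective is quadratic in ``t`` with Hessian ``A[j,l] = (u_j . u_l)
    B[j,l]`` and gradient ``b_j = u_j . (B X)_j``, both restricted to
    semilandmark rows.
    """
    Bsub = B[np.ix_(semis, semis)]
    A = (tangents @ tangents.T) * Bsub
    g = np.einsum("jc,jc->j", tangents, (B @ points)[semis])
    t, *_ = np.linalg.lstsq(A, -g, rcond=None)
    out = points.copy()
    out[semis] += t[:, None] * tangents
    return out


class SlidingSemilandmarks(TransformerMixin, BaseEstimator):
    """Slide semilandmarks against a fixed reference configuration.

    Parameters
    ----------
    reference : (k, 2) array_like or None
        Fixed average configuration sliding minimizes bending energy
        against.  If None, the Procrustes mean of the input sample is
        computed once at ``fit`` time (scaled back to the median centroid
        size so it lives on the scale of the data).
    max_iter : int
        Maximum sliding iterations per specimen.
    tol : float
        Stop when the relative bending-energy decrease falls below this.
    update_reference : bool
        Conventional alternating variant: recompute the reference as the
        Procrustes mean after each full pass and re-slide (default False —
        the reference is computed once and held fixed).
    n_reference_updates : int
        Number of outer reference refreshes when ``update_reference`` is on.
    slide_indices : sequence of int or None
        Restrict sliding to this subset of semilandmark indices; the
        remaining semilandmarks act as fixed anchors (default None: all
        semilandmarks slide).

    Attributes
    ----------
    reference_ : (k, 2) ndarray
        The reference actually used.
    energy_paths_ : list of list of float
        Bending energy against the reference at every iteration, per
        specimen (non-increasing by construction).
    n_iter_ : list of int
    """

    def __init__(self, reference=None, max_iter: int = 20, tol: float = 1e-6,
                 update_reference: bool = False, n_reference_updates: int = 3,
                 slide_indices=None):
        self.reference = reference
        self.max_iter = max_iter
        self.tol = tol
        self.update_reference = update_reference
        self.n_reference_updates = n_reference_updates
        self.slide_indices = slide_indices

    def _mean_reference(self, configs) -> np.ndarray:
        res = gpa([c.points for c in configs])
        scale = float(np.median(res.centroid_sizes))
        return res.mean_shape * scale

    def fit(self, X, y=None):
        configs = list(X)
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
        else:
            self.reference_ = self._mean_reference(configs)
        return self

    def transform(self, X) -> list:
        configs = list(X)
        rounds = (self.n_reference_updates if self.update_reference else 0) + 1
        reference = self.reference_
        for r in range(rounds):
            out, paths, iters = [], [], []
            for cfg in configs:
                slid, path = self._slide_specimen(cfg, reference)
                out.append(slid)
                paths.append(path)
                iters.append(len(path) - 1)
            configs = out
            if self.update_reference and r + 1 < rounds:
                reference = self._mean_reference(configs)
        self.energy_paths_ = paths
        self.n_iter_ = iters
        self.reference_ = reference
        return configs

    def fit_transform(self, X, y=None) -> list:
        return self.fit(X).transform(X)

    def _slide_specimen(self, config: LandmarkConfiguration,
                        reference: np.ndarray):
        if config.k != reference.shape[0]:
            raise ValueError(
                f"specimen '{config.specimen_id}' has {config.k} points but "
                f"the reference has {reference.shape[0]}")
        semis = config.semilandmark_indices
        if self.slide_indices is not None:
            wanted = np.asarray(sorted(self.slide_indices), dtype=int)
            if not np.isin(wanted, semis).all():
                raise ValueError("slide_indices must be semilandmarks")
            semis = wanted
        B = bending_energy_matrix(reference)
        aligned, params = ordinary_procrustes(config.points, reference)
        if not semis.size:
            return config, [bending_energy(B, aligned)]
        pts = aligned
        path = [bending_energy(B, pts)]
        for _ in range(self.max_iter):
            tangents = _tangents(config, pts, semis)
            candidate = _slide_once(pts, semis, tangents, B)
            energy = bending_energy(B, candidate)
            if energy > path[-1]:
                break  # numerically stuck; keep the last monotone iterate
            pts = candidate
            path.append(energy)
            prev = path[-2]
            if prev == 0.0 or (prev - energy) / prev < self.tol:
                break
        # Map slid coordinates back into the original digitizing frame.
        R, s, t = params["rotation"], params["scale"], params["translation"]
        original = (pts - t) @ R.T / s + config.points.mean(axis=0)
        original[config.anatomical_indices] = \
            config.points[config.anatomical_indices]
        return config.with_points(original), path


def slide_semilandmarks(configs, reference=None, max_iter: int = 20,
                        tol: float = 1e-6, **kwargs):
    """Slide each configuration's semilandmarks against a fixed reference.

    Thin wrapper over :class:`SlidingSemilandmarks`; returns the list of
    slid :class:`~gmia.landmarks.LandmarkConfiguration`.
    """
    est = SlidingSemilandmarks(reference=reference, max_iter=max_iter,
                               tol=tol, **kwargs)
    return est.fit_transform(configs)
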