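"""Ordinations of shape and texture: between-group PCA, scaled two-block
partial least squares, and permutation tests.

Between-group PCA (bgPCA) projects the individual observations orthogonally
onto the principal components of the *group means*.  The resulting g-1 axes
form an orthonormal basis of the subspace spanned by the centered group
means, so pairwise Euclidean distances among the projected group means equal
the distances among the original group means exactly — the property that
makes bgPCA a faithful low-dimensional ordination of group structure.
Applied to registered pixel intensities the loadings are *eigenimages*.

Shape coordinates and pixel intensities have no common scale, so a joint
PCA of both blocks is not meaningful.  The scaled two-block PLS instead
finds one unit-norm linear combination per block with maximal covariance
(the leading singular pair of the cross-covariance matrix), rescales the
two score vectors onto a common magnitude by major-axis regression, and
treats the combined scaled coefficient vectors as one joint factor.  Further
dimensions are obtained after projecting each block onto the orthogonal
complement of its earlier loadings (deflation).

Group differences are tested by permutation: the statistic is the Euclidean
distance between group mean vectors, and labels are shuffled preserving
group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .texture import TextureMap, map_from_vector


@dataclass
class DataBlock:
    """One block of per-specimen variables with group labels.

    ``matrix`` is n specimens x p variables — flattened Procrustes shape
    coordinates or flattened registered-image intensities.
    """

    matrix: np.ndarray
    variable_kind: str  # "shape" | "texture"
    group_labels: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (specimens x variables)")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains missing/non-finite values")
        labels = np.asarray(self.group_labels)
        if labels.shape != (m.shape[0],):
            raise ValueError("one group label per specimen required")
        self.matrix = m
        self.group_labels = labels


@dataclass
class OrdinationResult:
    """Axis loadings, per-specimen scores, and variance explained.

    ``axes`` columns are unit-norm loadings; ``variance_explained`` is the
    per-axis fraction of total individual variance.  bgPCA axes are ordered
    by group-mean variance, so individual variance explained need not be
    non-increasing.
    """

    axes: np.ndarray                 # (p, d)
    scores: np.ndarray               # (n, d)
    group_mean_scores: np.ndarray    # (g, d)
    variance_explained: np.ndarray   # (d,)
    center: np.ndarray               # (p,)
    group_order: tuple


@dataclass
class PLSResult:
    """Scaled two-block PLS output.

    Per dimension: unit-norm ``shape_vectors`` / ``texture_vectors``
    loadings, the major-axis-regression ``scaling_factors`` relating texture
    scores to shape scores, the ``singular_covariances`` (covariance of the
    paired score vectors, maximal by construction), block scores, and the
    ``joint_scores`` of the common factor.
    """

    shape_vectors: np.ndarray        # (p, d)
    texture_vectors: np.ndarray      # (q, d)
    scaling_factors: np.ndarray      # (d,)
    singular_covariances: np.ndarray # (d,)
    shape_scores: np.ndarray         # (n, d)
    texture_scores: np.ndarray       # (n, d)
    joint_scores: np.ndarray         # (n, d)


def _group_means(X: np.ndarray, labels: np.ndarray):
    groups = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    means = np.stack([X[labels == g].mean(axis=0) for g in groups])
    counts = np.array([(labels == g).sum() for g in groups])
    if (counts == 0).any():
        raise ValueError("every group needs at least one specimen")
    return groups, means


def _pin_signs(axes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = axes.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


class BetweenGroupPCA(TransformerMixin, BaseEstimator):
    """Between-group principal component analysis.

    Axes are the eigenvectors of the covariance of the group means
    (divisor g-1); individuals are orthogonally projected onto them.  At
    most g-1 axes exist.  Data are centered on the unweighted mean of the
    group means by default, so groups of unequal size are equitable;
    ``center="grand"`` centers on the grand mean of individuals instead.

    Attributes (after ``fit``)
    --------------------------
    components_ : (d, p) ndarray — unit-norm axes, sklearn orientation
    mean_ : (p,) centering vector
    group_means_ : (g, p)
    group_mean_scores_ : (g, d)
    explained_variance_ratio_ : (d,) fraction of total *individual* variance
    eigenvalues_ : (d,) group-mean variances along each axis
    groups_ : list of group labels in first-appearance order
    """

    def __init__(self, n_components: int | None = None,
                 center: str = "group_means"):
        self.n_components = n_components
        self.center = center

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("between-group PCA requires group labels y")
        X = np.asarray(X, dtype=float)
        labels = np.asarray(y)
        if X.shape[0] != labels.shape[0]:
            raise ValueError("X and y disagree in length")
        groups, means = _group_means(X, labels)
        g = len(groups)
        if g < 2:
            raise ValueError("need at least two groups")
        if self.center == "group_means":
            mu = means.mean(axis=0)
        elif self.center == "grand":
            mu = X.mean(axis=0)
        else:
            raise ValueError("center must be 'group_means' or 'grand'")
        d_max = g - 1
        d = d_max if self.n_components is None else int(self.n_components)
        if d > d_max or d < 1:
            raise ValueError(f"n_components must lie in [1, {d_max}] "
                             f"for {g} groups")
        centered_means = means - means.mean(axis=0)
        # Eigenvectors of the group-mean covariance via SVD of the g x p
        # mean matrix (the p x p covariance is never formed).
        _, svals, vt = np.linalg.svd(centered_means, full_matrices=False)
        axes = _pin_signs(vt[:d_max].T)[:, :d]
        eigenvalues = (svals[:d_max] ** 2 / (g - 1))[:d]
        Xc = X - mu
        scores = Xc @ axes
        total_var = float(np.sum(X.var(axis=0, ddof=1)))
        axis_var = scores.var(axis=0, ddof=1)
        self.components_ = axes.T
        self.mean_ = mu
        self.group_means_ = means
        self.group_mean_scores_ = (means - mu) @ axes
        self.eigenvalues_ = eigenvalues
        self.explained_variance_ratio_ = (
            axis_var / total_var if total_var > 0 else np.zeros(d))
        self.groups_ = groups
        self.scores_ = scores
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def result_(self) -> OrdinationResult:
        return OrdinationResult(
            axes=self.components_.T, scores=self.scores_,
            group_mean_scores=self.group_mean_scores_,
            variance_explained=self.explained_variance_ratio_,
            center=self.mean_, group_order=tuple(self.groups_),
        )


def between_group_pca(block: DataBlock, d: int | None = None,
                      center: str = "group_means") -> OrdinationResult:
    """Between-group PCA of a data block (functional wrapper)."""
    est = BetweenGroupPCA(n_components=d, center=center)
    est.fit(block.matrix, block.group_labels)
    return est.result_()


class ScaledPLS(BaseEstimator):
    """Scaled two-block partial least squares with orthogonal deflation.

    Dimension 1 is the leading singular pair of the between-block
    cross-covariance; its singular value equals the covariance of the two
    score vectors and is maximal over all unit-norm loading pairs.  Scores
    are put on a common magnitude by major-axis regression (first principal
    axis of the 2-D score scatter), with the sign chosen so shape and
    texture scores associate positively.  Later dimensions repeat the
    procedure on data deflated into the orthogonal complement of the earlier
    loadings of each block.

    The decomposition is computed through the n x n inner-product
    representation of each block, so texture blocks with far more pixels
    than specimens stay cheap.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("blocks must be 2-D matrices")
        n = X.shape[0]
        if Y.shape[0] != n:
            raise ValueError("blocks must describe the same specimens")
        if n < 3:
            raise ValueError("need at least 3 specimens")
        d = int(self.n_components)
        rank_cap = min(n - 1, X.shape[1], Y.shape[1])
        if d < 1 or d > rank_cap:
            raise ValueError(f"n_components must lie in [1, {rank_cap}]")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        # Economy SVD bases: block = scores_in_basis @ basis^T.
        ux, sx, vxt = np.linalg.svd(Xc, full_matrices=False)
        uy, sy, vyt = np.linalg.svd(Yc, full_matrices=False)
        Tx = ux * sx            # (n, rx) coefficients in basis vx
        Ty = uy * sy
        Vx = vxt.T              # (p, rx)
        Vy = vyt.T
        p, q = X.shape[1], Y.shape[1]
        U = np.zeros((p, d))
        V = np.zeros((q, d))
        covs = np.zeros(d)
        scales = np.zeros(d)
        sxs = np.zeros((n, d))
        sys_ = np.zeros((n, d))
        for dim in range(d):
            W = Tx.T @ Ty / (n - 1)
            a_mat, svals, bt = np.linalg.svd(W)
            a = a_mat[:, 0]
            b = bt[0]
            sigma = svals[0]
            if sigma < 1e-14:
                warnings.warn("cross-covariance is (numerically) zero; "
                              "remaining PLS dimensions are arbitrary",
                              RuntimeWarning, stacklevel=2)
            u = Vx @ a
            v = Vy @ b
            # Sign conventions: pin u by its largest component, then flip v
            # so the score covariance is non-negative.
            i = int(np.argmax(np.abs(u)))
            if u[i] < 0:
                u, a = -u, -a
                v, b = -v, -b
            score_x = Tx @ a
            score_y = Ty @ b
            if float(score_x @ score_y) < 0:
                v, b = -v, -b
                score_y = -score_y
            U[:, dim] = u
            V[:, dim] = v
            covs[dim] = float(score_x @ score_y) / (n - 1)
            scales[dim] = _major_axis_slope(score_x, score_y)
            sxs[:, dim] = score_x
            sys_[:, dim] = score_y
            # Deflate within the reduced bases: project out a and b.
            Tx = Tx - np.outer(Tx @ a, a)
            Ty = Ty - np.outer(Ty @ b, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            rescaled = np.where(scales != 0, sys_ / scales, sys_)
        self.x_loadings_ = U
        self.y_loadings_ = V
        self.covariances_ = covs
        self.scaling_factors_ = scales
        self.x_scores_ = sxs
        self.y_scores_ = sys_
        self.joint_scores_ = (sxs + rescaled) / 2.0
        return self

    def transform(self, X, Y=None):
        sx = (np.asarray(X, float) - self.x_mean_) @ self.x_loadings_
        if Y is None:
            return sx
        sy = (np.asarray(Y, float) - self.y_mean_) @ self.y_loadings_
        return sx, sy

    def result_(self) -> PLSResult:
        return PLSResult(
            shape_vectors=self.x_loadings_, texture_vectors=self.y_loadings_,
            scaling_factors=self.scaling_factors_,
            singular_covariances=self.covariances_,
            shape_scores=self.x_scores_, texture_scores=self.y_scores_,
            joint_scores=self.joint_scores_,
        )


def _major_axis_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope of the first principal axis of the centered 2-D scatter (x, y).

    Unlike ordinary regression this treats both variables symmetrically,
    which is what putting two arbitrarily scaled score vectors on a common
    magnitude requires.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    cov = np.array([[xc @ xc, xc @ yc], [xc @ yc, yc @ yc]])
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, 1]
    if v[0] == 0:
        return np.inf
    slope = v[1] / v[0]
    return float(abs(slope)) if (xc @ yc) >= 0 else float(-abs(slope))


def scaled_pls(shape_block: DataBlock, texture_block: DataBlock,
               d: int = 2) -> PLSResult:
    """Scaled two-block PLS of shape against texture (functional wrapper)."""
    est = ScaledPLS(n_components=d).fit(shape_block.matrix,
                                        texture_block.matrix)
    return est.result_()


def permutation_test(block: DataBlock, group_a, group_b, n_perm: int = 999,
                     seed: int | None = None, method: str = "random"):
    """Permutation test of a two-group mean difference.

    The statistic is the Euclidean distance between the two group mean
    vectors.  Group labels are permuted preserving group sizes.  The
    add-one estimator ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``
    avoids zero p-values; with ``method="exact"`` all distinct assignments
    of pooled rows to group a are enumerated instead and
    ``p = #{splits >= observed} / n_splits`` (the identity split counts).

    Returns
    -------
    p_value : float
    observed : float
    """
    labels = np.asarray(block.group_labels)
    A = block.matrix[labels == group_a]
    B = block.matrix[labels == group_b]
    na, nb = A.shape[0], B.shape[0]
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.vstack([A, B])
    observed = float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    if method == "exact":
        stats = []
        for idx_a in combinations(range(na + nb), na):
            sel = np.zeros(na + nb, dtype=bool)
            sel[list(idx_a)] = True
            stat = np.linalg.norm(pooled[sel].mean(axis=0)
                                  - pooled[~sel].mean(axis=0))
            stats.append(stat)
        stats = np.asarray(stats)
        p = float(np.count_nonzero(stats >= observed - 1e-12) / stats.size)
        return p, observed
    if method != "random":
        raise ValueError("method must be 'random' or 'exact'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(na + nb)
        pa = pooled[perm[:na]]
        pb = pooled[perm[na:]]
        stat = np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0))
        if stat >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(p), observed


def pairwise_permutation_tests(block: DataBlock, n_perm: int = 999,
                               seed: int | None = None) -> dict:
    """Permutation tests for every pair of groups in a block."""
    groups = list(dict.fromkeys(np.asarray(block.group_labels).tolist()))
    rng = np.random.default_rng(seed)
    out = {}
    for ga, gb in combinations(groups, 2):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        p, stat = permutation_test(block, ga, gb, n_perm=n_perm,
                                   seed=sub_seed)
        out[(ga, gb)] = {"p_value": p, "observed": stat}
    return out


def eigenimage_render(result: OrdinationResult, axis: int, score: float,
                      mean: TextureMap, index_map: np.ndarray) -> TextureMap:
    """Texture reconstructed at a score along one bgPCA axis.

    Adds ``score`` times the axis loading (an eigenimage) to the mean
    texture map and clips to [0, 1] for display, recording the clipped
    fraction on the returned map.
    """
    if axis >= result.axes.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    loading = result.axes[:, axis]
    if index_map.shape[0] != loading.shape[0]:
        raise ValueError("index map inconsistent with loading length")
    delta = map_from_vector(loading * score, index_map, mean.grid.shape)
    raw = mean.grid + delta.grid
    clipped = np.clip(raw, 0.0, 1.0)
    valid = mean.mask & delta.mask
    n_valid = int(valid.sum())
    frac = float(np.count_nonzero(raw[valid] != clipped[valid]) / n_valid) \
        if n_valid else 0.0
    grid = np.where(valid, clipped, 0.0)
    return TextureMap(grid=grid, kind="mean", mask=valid, clip_fraction=frac)


def shape_reconstruction(result: OrdinationResult, axis: int, score: float,
                         mean_shape: np.ndarray) -> np.ndarray:
    """Shape reconstructed at a score along one bgPCA axis.

    The axis loading over flattened (x0 y0 x1 y1 ...) shape coordinates is
    reshaped to (k, 2) and added to the mean shape scaled by ``score``.
    """
    if axis >= result.axes.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    mean_shape = np.asarray(mean_shape, dtype=float)
    loading = result.axes[:, axis]
    if loading.shape[0] != mean_shape.size:
        raise ValueError("loading length inconsistent with mean shape")
    return mean_shape + score * loading.reshape(mean_shape.shape)
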