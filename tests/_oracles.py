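"""Independent oracle implementations used only by the tests.

Everything here is written deliberately differently from the package: the
TPS system is assembled element by element with explicit loops and solved
with scipy, the two-shape Procrustes solution uses the standard SVD
closed form written from scratch, and the small ordination oracles form the
dense covariance matrices the package avoids.  These routines exist so the
package can be checked against a second, plainly-readable derivation.
"""

import math

import numpy as np
import scipy.linalg


def dense_tps_solve(source, target):
    """Solve the full (k+3)x(k+3) TPS system with explicit loops.

    Returns (weights, affine, bending_energy, L, K).
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    k = source.shape[0]
    K = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            r = math.hypot(source[i, 0] - source[j, 0],
                           source[i, 1] - source[j, 1])
            K[i, j] = r * r * math.log(r) if r > 0 else 0.0
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    for i in range(k):
        L[i, k] = L[k, i] = 1.0
        L[i, k + 1] = L[k + 1, i] = source[i, 0]
        L[i, k + 2] = L[k + 2, i] = source[i, 1]
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    sol = scipy.linalg.solve(L, rhs)
    w = sol[:k]
    affine = sol[k:]
    be = 0.0
    for c in range(2):
        be += float(w[:, c] @ K @ w[:, c])
    return w, affine, be, L, K


def dense_tps_eval(source, weights, affine, points):
    """Evaluate the dense-oracle TPS at query points, loops and all."""
    source = np.asarray(source, float)
    points = np.atleast_2d(np.asarray(points, float))
    out = np.zeros_like(points)
    for m, p in enumerate(points):
        for c in range(2):
            val = affine[0, c] + affine[1, c] * p[0] + affine[2, c] * p[1]
            for j, s in enumerate(source):
                r = math.hypot(p[0] - s[0], p[1] - s[1])
                if r > 0:
                    val += weights[j, c] * r * r * math.log(r)
            out[m, c] = val
    return out


def dense_bending_energy(source, target):
    """Bending energy from the dense system (summed over coordinates)."""
    return dense_tps_solve(source, target)[2]


def dense_bending_energy_matrix(source):
    """Upper-left k x k block of the inverse bordered system."""
    k = np.asarray(source).shape[0]
    L = dense_tps_solve(source, np.asarray(source, float))[3]
    return np.linalg.inv(L)[:k, :k]


def two_shape_procrustes(a, b):
    """Closed-form ordinary Procrustes of `a` onto `b` (rotation only, no
    reflection, unit-size shapes).  Returns the aligned `a` and the residual
    distance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac = ac / np.sqrt((ac ** 2).sum())
    bc = bc / np.sqrt((bc ** 2).sum())
    u, _, vt = np.linalg.svd(ac.T @ bc)
    s = np.sign(np.linalg.det(u @ vt))
    R = u @ np.diag([1.0, s]) @ vt
    aligned = ac @ R
    return aligned, float(np.sqrt(((aligned - bc) ** 2).sum()))


def bgpca_dense_oracle(X, labels, d):
    """Between-group PCA by forming the dense group-mean covariance."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()), key=labels.tolist().index)
    means = np.stack([X[labels == g].mean(axis=0) for g in groups])
    mu = means.mean(axis=0)
    cov = (means - mu).T @ (means - mu) / (len(groups) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    axes = vecs[:, order[:d]]
    scores = (X - mu) @ axes
    mean_scores = (means - mu) @ axes
    return axes, scores, mean_scores


def pls_dense_oracle(X, Y):
    """First singular pair of the dense cross-covariance via an explicit
    2x2 (or qxq) eigensolve of C^T C."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    C = Xc.T @ Yc / (n - 1)
    CtC = C.T @ C
    vals, vecs = np.linalg.eigh(CtC)
    v = vecs[:, np.argmax(vals)]
    sigma = math.sqrt(max(float(vals.max()), 0.0))
    u = C @ v
    nu = np.linalg.norm(u)
    if nu > 0:
        u = u / nu
    return u, v, sigma
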