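"""Landmark configurations, curve bookkeeping, and TPS-file I/O.

A configuration holds the ordered 2-D points digitized on one specimen,
split into *anatomical* landmarks (point homology given by anatomy) and
*semilandmarks* (points on open curves whose along-curve position is
estimated later by sliding).  Files follow the tpsDig text dialect::

    LM=4
    12.0 30.5
    ...
    CURVES=2
    POINTS=10
    ...
    POINTS=12
    ...
    IMAGE=specimen01.png
    ID=0

Points in the ``LM`` block are anatomical; each ``POINTS`` block is one open
curve of semilandmarks, listed in along-curve order.  tpsDig coordinates are
y-up with the origin at the bottom-left of the image; image arrays in this
package are row-major with the origin top-left.  :func:`flip_y` converts
between the two given the image height (see the image_registration docs for
the pixel-center convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

ANATOMICAL = "anatomical"
SEMILANDMARK = "semilandmark"


@dataclass(frozen=True)
class CurveSpec:
    """One open curve: indices into the configuration, in along-curve order."""

    point_indices: tuple
    closed: bool = False

    def __post_init__(self):
        object.__setattr__(self, "point_indices",
                           tuple(int(i) for i in self.point_indices))
        if len(self.point_indices) < 2:
            raise ValueError("a curve needs at least 2 points")
        if len(set(self.point_indices)) != len(self.point_indices):
            raise ValueError("curve point indices must be distinct")
        if self.closed:
            raise ValueError("closed curves are not supported")


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's landmarks, roles, and curve membership.

    Attributes
    ----------
    points : (k, 2) ndarray
    roles : (k,) ndarray of str
        Either ``"anatomical"`` or ``"semilandmark"`` per point.
    curves : tuple of CurveSpec
        Every semilandmark belongs to exactly one curve; anatomical
        landmarks belong to none.
    specimen_id : str
    image_path : str or None
    """

    points: np.ndarray
    roles: np.ndarray
    curves: tuple = ()
    specimen_id: str = ""
    image_path: str | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        roles = np.asarray(self.roles, dtype=object)
        if roles.shape != (pts.shape[0],):
            raise ValueError("roles must have one entry per point")
        bad = set(roles) - {ANATOMICAL, SEMILANDMARK}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        curves = tuple(self.curves)
        k = pts.shape[0]
        seen: dict[int, int] = {}
        for ci, curve in enumerate(curves):
            for idx in curve.point_indices:
                if not 0 <= idx < k:
                    raise ValueError(f"curve {ci} references point {idx} "
                                     f"outside configuration of size {k}")
                if idx in seen:
                    raise ValueError(f"point {idx} belongs to curves "
                                     f"{seen[idx]} and {ci}")
                if roles[idx] != SEMILANDMARK:
                    raise ValueError(
                        f"curve {ci} contains point {idx} with role "
                        f"'{roles[idx]}'; curves may only hold semilandmarks")
                seen[idx] = ci
        orphans = [i for i in range(k)
                   if roles[i] == SEMILANDMARK and i not in seen]
        if orphans:
            raise ValueError(f"semilandmarks {orphans} belong to no curve")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "roles", roles)
        object.__setattr__(self, "curves", curves)

    @property
    def k(self) -> int:
        return self.points.shape[0]

    @property
    def is_semilandmark(self) -> np.ndarray:
        return self.roles == SEMILANDMARK

    @property
    def anatomical_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ANATOMICAL)

    @property
    def semilandmark_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == SEMILANDMARK)

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        """Copy of this configuration with replaced coordinates."""
        return replace(self, points=np.asarray(points, dtype=float))

    def curve_neighbors(self, index: int) -> tuple[int | None, int | None]:
        """Along-curve neighbors (previous, next) of a semilandmark."""
        for curve in self.curves:
            if index in curve.point_indices:
                pos = curve.point_indices.index(index)
                prev = curve.point_indices[pos - 1] if pos > 0 else None
                nxt = (curve.point_indices[pos + 1]
                       if pos + 1 < len(curve.point_indices) else None)
                return prev, nxt
        raise ValueError(f"point {index} belongs to no curve")


def flip_y(points, image_height: int) -> np.ndarray:
    """Convert between y-up (tpsDig) and row-down (array) frames.

    With pixel centers at integer coordinates ``0 .. H-1``, the map is
    ``y' = (H - 1) - y`` and is its own inverse.
    """
    pts = np.asarray(points, dtype=float).copy()
    pts[..., 1] = (image_height - 1) - pts[..., 1]
    return pts


def _format_point(p) -> str:
    return f"{p[0]:.6f} {p[1]:.6f}"


def write_tps(path, configs) -> None:
    """Write configurations in the tpsDig text dialect.

    Anatomical landmarks go to the ``LM`` block and each curve to a
    ``POINTS`` block, so role/curve structure round-trips through
    :func:`read_tps`.
    """
    lines = []
    for i, cfg in enumerate(configs):
        anat = cfg.anatomical_indices
        lines.append(f"LM={len(anat)}")
        for idx in anat:
            lines.append(_format_point(cfg.points[idx]))
        if cfg.curves:
            lines.append(f"CURVES={len(cfg.curves)}")
            for curve in cfg.curves:
                lines.append(f"POINTS={len(curve.point_indices)}")
                for idx in curve.point_indices:
                    lines.append(_format_point(cfg.points[idx]))
        if cfg.image_path:
            lines.append(f"IMAGE={cfg.image_path}")
        lines.append(f"ID={cfg.specimen_id or i}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_tps(path):
    """Read a tpsDig-dialect landmark file.

    Returns a list of :class:`LandmarkConfiguration`.  ``LM`` points are
    anatomical, ``POINTS`` blocks are open curves of semilandmarks.  ``SCALE``
    records are ignored.  Note tpsDig files are y-up; convert with
    :func:`flip_y` before pairing with image arrays.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    configs = []
    i = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise ValueError(f"expected LM= record at line {i + 1}: {lines[i]!r}")
        n_anat = int(lines[i].split("=", 1)[1])
        i += 1
        anat_pts = []
        for _ in range(n_anat):
            x, y = lines[i].split()[:2]
            anat_pts.append((float(x), float(y)))
            i += 1
        curve_blocks = []
        if i < len(lines) and lines[i].upper().startswith("CURVES="):
            n_curves = int(lines[i].split("=", 1)[1])
            i += 1
            for _ in range(n_curves):
                if not lines[i].upper().startswith("POINTS="):
                    raise ValueError(f"expected POINTS= at line {i + 1}")
                n_pts = int(lines[i].split("=", 1)[1])
                i += 1
                pts = []
                for _ in range(n_pts):
                    x, y = lines[i].split()[:2]
                    pts.append((float(x), float(y)))
                    i += 1
                curve_blocks.append(pts)
        image_path = None
        specimen_id = ""
        while i < len(lines):
            upper = lines[i].upper()
            if upper.startswith("IMAGE="):
                image_path = lines[i].split("=", 1)[1]
                i += 1
            elif upper.startswith("SCALE="):
                i += 1
            elif upper.startswith("ID="):
                specimen_id = lines[i].split("=", 1)[1]
                i += 1
                break
            elif upper.startswith("LM="):
                break
            else:
                raise ValueError(f"unexpected record at line {i + 1}: {lines[i]!r}")
        points = list(anat_pts)
        roles = [ANATOMICAL] * n_anat
        curves = []
        for pts in curve_blocks:
            start = len(points)
            points.extend(pts)
            roles.extend([SEMILANDMARK] * len(pts))
            curves.append(CurveSpec(tuple(range(start, start + len(pts)))))
        configs.append(LandmarkConfiguration(
            points=np.asarray(points, dtype=float),
            roles=np.asarray(roles, dtype=object),
            curves=tuple(curves),
            specimen_id=specimen_id,
            image_path=image_path,
        ))
    return configs


def read_roles_sidecar(path, configs):
    """Apply a JSON sidecar with role/curve metadata to bare configurations.

    Used when the TPS dialect carries all points in a single ``LM`` block.
    Schema::

        {"roles": ["anatomical", "semilandmark", ...],
         "curves": [[4, 5, 6, ...], ...]}
    """
    with open(path) as fh:
        meta = json.load(fh)
    roles = np.asarray(meta["roles"], dtype=object)
    curves = tuple(CurveSpec(tuple(ix)) for ix in meta.get("curves", []))
    return [replace(cfg, roles=roles, curves=curves) for cfg in configs]
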