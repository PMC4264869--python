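"""Registering specimen images to the sample mean shape by TPS unwarping.

After Procrustes superimposition of the landmarks, each specimen's image is
resampled onto the pixel grid of the grand-mean shape so that pixels become
comparable across specimens.  Resampling uses *backward warping*: a TPS is
fitted from the mean-shape (template) landmarks to the specimen landmarks,
every template pixel center is mapped into the specimen image, and the
intensity there is interpolated.  Backward warping yields exactly one sample
per output pixel — no holes in areas of expansion, no pile-ups in areas of
compression.  Template pixels whose preimage falls outside the specimen
image are flagged in a validity mask and excluded from all downstream
statistics.

Coordinate convention: image arrays are row-major with the origin at the
top-left and pixel centers at integer coordinates; a landmark ``(x, y)``
addresses column ``x``, row ``y``.  Landmark files digitized y-up must be
flipped with :func:`gmia.landmarks.flip_y` before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .procrustes import ProcrustesResult
from .tps import tps_apply, tps_fit

_INTERP_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}

#: Preimages within this many pixels outside the source bounds are treated
#: as inside (and clipped): TPS evaluation carries ~1e-14 float noise that
#: must not knock border pixels out of the valid mask.
BOUNDS_TOL = 1e-6


@dataclass
class SpecimenImage:
    """A raw specimen image with intensities scaled to [0, 1].

    ``pixels`` is ``(H, W)`` grayscale or ``(H, W, 3)`` RGB; ``pixel_size``
    is an optional physical calibration (µm/px) carried through unchanged.
    """

    pixels: np.ndarray
    specimen_id: str = ""
    pixel_size: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) or (H, W, 3)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def shape(self):
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class RegisteredImage:
    """A specimen image resampled onto the mean-shape template grid.

    Pixels outside ``valid_mask`` hold the sentinel fill value (0) and must
    be excluded from statistics; all registered images of a sample share the
    same grid.
    """

    pixels: np.ndarray
    valid_mask: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        if self.valid_mask.shape != self.pixels.shape[:2]:
            raise ValueError("valid_mask must match the pixel grid")

    @property
    def shape(self):
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


def load_image(path, specimen_id: str = "") -> SpecimenImage:
    """Read a PNG/TIFF image, scaling 8/16-bit integers to [0, 1] floats."""
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]  # drop alpha
    if np.issubdtype(raw.dtype, np.integer):
        px = raw.astype(float) / np.iinfo(raw.dtype).max
    else:
        px = np.clip(raw.astype(float), 0.0, 1.0)
    return SpecimenImage(pixels=px, specimen_id=specimen_id or str(path))


def unwarp_image(image: SpecimenImage, specimen_landmarks, mean_landmarks,
                 template_size, *, interp: str = "bilinear",
                 fill: float = 0.0) -> RegisteredImage:
    """Backward-warp one specimen image onto the template grid.

    A TPS is fitted from ``mean_landmarks`` (template pixel frame) to
    ``specimen_landmarks`` (specimen pixel frame); each template pixel center
    is mapped through it and the specimen image is sampled there
    (bilinear by default).  By construction the digitized structures come to
    rest exactly on the template's mean-shape landmark positions.

    Parameters
    ----------
    template_size : (H', W')
        Output grid size in pixels.
    interp : {"bilinear", "nearest", "bicubic"}
    fill : float
        Sentinel written at invalid (out-of-bounds) pixels.
    """
    if interp not in _INTERP_ORDERS:
        raise ValueError(f"interp must be one of {sorted(_INTERP_ORDERS)}")
    spec = np.asarray(specimen_landmarks, dtype=float)
    mean = np.asarray(mean_landmarks, dtype=float)
    if spec.shape != mean.shape:
        raise ValueError("landmark sets must have matching counts")
    h, w = int(template_size[0]), int(template_size[1])
    transform = tps_fit(mean, spec)
    gy, gx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    pre = tps_apply(transform, centers)              # (m, 2) x, y in source
    src_h, src_w = image.shape
    x, y = pre[:, 0], pre[:, 1]
    valid = ((x >= -BOUNDS_TOL) & (x <= src_w - 1 + BOUNDS_TOL)
             & (y >= -BOUNDS_TOL) & (y <= src_h - 1 + BOUNDS_TOL))
    coords = np.array([np.clip(y, 0, src_h - 1),     # row, col for ndimage
                       np.clip(x, 0, src_w - 1)])
    order = _INTERP_ORDERS[interp]
    if image.n_channels == 1:
        flat = ndimage.map_coordinates(image.pixels, coords, order=order,
                                       mode="constant", cval=fill)
        out = flat.reshape(h, w)
    else:
        chans = [ndimage.map_coordinates(image.pixels[:, :, c], coords,
                                         order=order, mode="constant",
                                         cval=fill).reshape(h, w)
                 for c in range(3)]
        out = np.stack(chans, axis=2)
    mask = valid.reshape(h, w)
    out[~mask] = fill
    return RegisteredImage(pixels=out, valid_mask=mask,
                           specimen_id=image.specimen_id)


def template_frame(procrustes: ProcrustesResult, template_scale="median",
                   margin: float = 0.05):
    """Place the mean shape into a pixel frame for registration.

    The unit-size mean shape is scaled to ``template_scale`` — the median of
    the specimens' centroid sizes by default, preserving native pixel detail
    — and translated so its bounding box sits inside the grid with a
    ``margin`` fraction of padding per side.

    Returns
    -------
    mean_landmarks_px : (k, 2) ndarray
    template_size : (H', W') tuple of int
    """
    if template_scale == "median":
        scale = float(np.median(procrustes.centroid_sizes))
    else:
        scale = float(template_scale)
        if scale <= 0:
            raise ValueError("template_scale must be positive")
    shape = procrustes.mean_shape * scale
    lo = shape.min(axis=0)
    hi = shape.max(axis=0)
    span = hi - lo
    pad = margin * span
    landmarks = shape - lo + pad
    w = int(np.ceil(span[0] + 2 * pad[0])) + 1
    h = int(np.ceil(span[1] + 2 * pad[1])) + 1
    return landmarks, (h, w)


def register_sample(images, configs, procrustes: ProcrustesResult,
                    template_scale="median", margin: float = 0.05,
                    interp: str = "bilinear"):
    """Unwarp every specimen image to the common mean-shape grid.

    Parameters
    ----------
    images : list of SpecimenImage
    configs : list of LandmarkConfiguration or (k, 2) arrays
        Landmarks in each specimen's pixel frame, one per image, in the
        same order used to compute ``procrustes``.
    procrustes : ProcrustesResult

    Returns
    -------
    registered : list of RegisteredImage (all sharing one grid)
    mean_landmarks_px : (k, 2) ndarray — the mean shape in the template frame
    """
    if len(images) != len(configs):
        raise ValueError("need exactly one landmark configuration per image")
    mean_px, size = template_frame(procrustes, template_scale, margin)
    out = []
    for img, cfg in zip(images, configs):
        pts = cfg.points if hasattr(cfg, "points") else np.asarray(cfg, float)
        out.append(unwarp_image(img, pts, mean_px, size, interp=interp))
    return out, mean_px


def preimage_coordinates(specimen_landmarks, mean_landmarks,
                         template_size) -> np.ndarray:
    """Map every template pixel center into the specimen frame.

    Exposes the raw backward-warp coordinate field for mask verification and
    diagnostics; returns an ``(H', W', 2)`` array of (x, y) source positions.
    """
    spec = np.asarray(specimen_landmarks, dtype=float)
    mean = np.asarray(mean_landmarks, dtype=float)
    h, w = int(template_size[0]), int(template_size[1])
    transform = tps_fit(mean, spec)
    gy, gx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    return tps_apply(transform, centers).reshape(h, w, 2)
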