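"""Pixelwise texture statistics on registered images.

Once all images share the mean-shape grid, the pixel values ("texture")
become a second block of variables alongside the Procrustes shape
coordinates.  Under a nuclear stain, pixel brightness is a proxy for local
cell density: the denser the projected nuclei, the darker the pixel.  This
module scalarizes RGB to brightness (the unweighted channel mean), computes
pixelwise sample means, variances and group-difference maps, and flattens
registered images into texture vectors for ordination.

All statistics are restricted to the *joint* valid mask — the set of pixels
whose preimage fell inside the source image for every specimen — so border
artifacts never contaminate the maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndimage

from .registration import RegisteredImage


@dataclass
class TextureMap:
    """A per-pixel statistic on the template grid.

    ``kind`` is one of ``"mean"``, ``"group_difference"`` or ``"variance"``;
    difference maps are signed, variance maps non-negative.  ``clip_fraction``
    is populated by rendering helpers that clamp values into [0, 1].
    """

    grid: np.ndarray
    kind: str
    mask: np.ndarray
    clip_fraction: float | None = None


@dataclass
class TextureVector:
    """Flattened intensities over the common valid-pixel set.

    ``pixel_index_map`` holds the (row, col) of each vector position and is
    identical for every specimen of a sample, so vectors are directly
    comparable and maps can be reassembled from loadings.
    """

    values: np.ndarray
    channel_mode: str
    pixel_index_map: np.ndarray  # (m, 2) ints

    @property
    def m(self) -> int:
        return self.values.shape[0]


def brightness(pixels) -> np.ndarray:
    """Scalarize an RGB image to brightness: the per-pixel channel mean.

    Grayscale input passes through unchanged; any other channel count is an
    error.
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 2:
        return px
    if px.ndim == 3 and px.shape[2] == 1:
        return px[:, :, 0]
    if px.ndim == 3 and px.shape[2] == 3:
        return px.mean(axis=2)
    raise ValueError(f"expected 1 or 3 channels, got shape {px.shape}")


def joint_valid_mask(sample) -> np.ndarray:
    """Intersection of the validity masks of all registered images."""
    sample = list(sample)
    if not sample:
        raise ValueError("empty sample")
    _check_grids(sample)
    mask = np.ones(sample[0].shape, dtype=bool)
    for img in sample:
        mask &= img.valid_mask
    return mask


def _check_grids(sample) -> None:
    shapes = {img.pixels.shape for img in sample}
    if len(shapes) > 1:
        raise ValueError(f"registered images disagree in grid: {shapes}")


def _stack(sample, channel_mode: str) -> np.ndarray:
    if channel_mode not in ("brightness", "rgb"):
        raise ValueError("channel_mode must be 'brightness' or 'rgb'")
    if channel_mode == "brightness":
        return np.stack([brightness(img.pixels) for img in sample])
    return np.stack([img.pixels for img in sample])


def smooth_registered(image: RegisteredImage, sigma: float) -> RegisteredImage:
    """Optional Gaussian pre-smoothing of a registered image (masked pixels
    are excluded by renormalized convolution)."""
    if sigma <= 0:
        return image
    mask = image.valid_mask.astype(float)
    def _smooth(plane):
        num = _ndimage.gaussian_filter(plane * mask, sigma)
        den = _ndimage.gaussian_filter(mask, sigma)
        out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        return out * image.valid_mask
    if image.pixels.ndim == 2:
        px = _smooth(image.pixels)
    else:
        px = np.stack([_smooth(image.pixels[:, :, c]) for c in range(3)], axis=2)
    return RegisteredImage(pixels=px, valid_mask=image.valid_mask.copy(),
                           specimen_id=image.specimen_id)


def mean_texture(sample, channel_mode: str = "brightness") -> TextureMap:
    """Pixelwise mean over specimens, restricted to jointly valid pixels.

    With ``channel_mode="rgb"`` the mean is computed separately per color
    channel; with ``"brightness"`` images are scalarized first.
    """
    sample = list(sample)
    mask = joint_valid_mask(sample)
    stack = _stack(sample, channel_mode)
    grid = stack.mean(axis=0)
    grid[~mask] = 0.0
    return TextureMap(grid=grid, kind="mean", mask=mask)


def variance_texture(sample, channel_mode: str = "brightness") -> TextureMap:
    """Pixelwise sample variance (denominator n-1) of brightness.

    Requires at least two specimens; the result is non-negative everywhere
    and zero outside the joint valid mask.
    """
    sample = list(sample)
    if len(sample) < 2:
        raise ValueError("variance needs at least two images")
    mask = joint_valid_mask(sample)
    stack = _stack(sample, channel_mode)
    grid = stack.var(axis=0, ddof=1)
    grid[~mask] = 0.0
    return TextureMap(grid=grid, kind="variance", mask=mask)


def group_difference_map(group_a, group_b,
                         channel_mode: str = "brightness") -> TextureMap:
    """Pixelwise difference of group means: ``mean(group_b) - mean(group_a)``.

    Sign convention: positive values mean group b is *brighter*, which under
    a nuclear stain corresponds to *lower* cell density; plots should flag
    this in their legends.  The conventional orientation is later group minus
    earlier group, so developmental density increases come out negative.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    _check_grids(group_a + group_b)
    mask = joint_valid_mask(group_a + group_b)
    stack_a = _stack(group_a, channel_mode)
    stack_b = _stack(group_b, channel_mode)
    grid = stack_b.mean(axis=0) - stack_a.mean(axis=0)
    grid[~mask] = 0.0
    return TextureMap(grid=grid, kind="group_difference", mask=mask)


def texture_matrix(sample, channel_mode: str = "brightness"):
    """Flatten a registered sample into an (n, m) matrix over valid pixels.

    Returns the matrix together with the shared ``(m, 2)`` pixel index map
    (row, col per column of the matrix).  With ``channel_mode="rgb"`` each
    valid pixel contributes three consecutive columns and the index map
    repeats accordingly.
    """
    sample = list(sample)
    mask = joint_valid_mask(sample)
    rows, cols = np.nonzero(mask)
    index_map = np.column_stack([rows, cols])
    stack = _stack(sample, channel_mode)
    if channel_mode == "rgb" and stack.ndim == 4:
        matrix = stack[:, rows, cols, :].reshape(len(sample), -1)
        index_map = np.repeat(index_map, 3, axis=0)
    else:
        matrix = stack[:, rows, cols]
    return matrix, index_map


def texture_vectors(sample, channel_mode: str = "brightness"):
    """Per-specimen :class:`TextureVector` objects over the joint mask."""
    matrix, index_map = texture_matrix(sample, channel_mode)
    return [TextureVector(values=row, channel_mode=channel_mode,
                          pixel_index_map=index_map) for row in matrix]


def map_from_vector(values: np.ndarray, index_map: np.ndarray,
                    grid_shape, kind: str = "mean",
                    fill: float = 0.0) -> TextureMap:
    """Reassemble a flattened texture vector into a grid map."""
    if index_map.shape[0] != values.shape[0]:
        raise ValueError("index map and vector lengths disagree "
                         "(rgb vectors must be scalarized first)")
    grid = np.full(grid_shape, fill, dtype=float)
    mask = np.zeros(grid_shape, dtype=bool)
    grid[index_map[:, 0], index_map[:, 1]] = values
    mask[index_map[:, 0], index_map[:, 1]] = True
    return TextureMap(grid=grid, kind=kind, mask=mask)
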