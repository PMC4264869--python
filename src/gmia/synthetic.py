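"""Synthetic multi-group samples of outline-defined 2-D specimens.

Every stage of the pipeline — sliding, Procrustes superimposition, image
unwarping, texture statistics, ordination — needs inputs whose truth is
known.  This module renders a "fin-like" specimen: a half-elliptical fin
outline and a straight midline band (sharp structures digitized by
landmarks and open semilandmark curves) over a smooth intensity background
(diffuse structure), deformed per specimen by a known thin-plate spline and
overlaid with known group texture effects and spatially structured
individual variation.

The study design emulated is a three-group cross-sectional sample of sizes
7/8/5 with group differences in both shape (a smooth elongation/narrowing
field of increasing magnitude) and texture (a darkening Gaussian blob of
increasing amplitude).  Semilandmarks are additionally jittered *along* the
local curve tangent, so the sliding algorithm has real work with a
recoverable ground truth (the unjittered position).

Rendering inverts each specimen's forward deformation numerically (Newton)
and evaluates the planted analytic field at the preimage of every
supersampled pixel center, then box-downsamples 4x, so sharp edges are
consistently anti-aliased and the backward-warp round trip of the
registration stage is exact up to interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import (ANATOMICAL, SEMILANDMARK, CurveSpec,
                        LandmarkConfiguration)
from .registration import SpecimenImage
from .tps import TPSTransform, tps_apply, tps_fit, tps_inverse


@dataclass(frozen=True)
class GaussianBlob:
    """An isotropic Gaussian intensity bump: amplitude * exp(-r^2 / 2 sigma^2)."""

    center: tuple
    sigma: float
    amplitude: float

    def __call__(self, x, y):
        r2 = (np.asarray(x, float) - self.center[0]) ** 2 \
            + (np.asarray(y, float) - self.center[1]) ** 2
        return self.amplitude * np.exp(-r2 / (2.0 * self.sigma ** 2))


def analytic_field(name: str, **params):
    """Closed-form intensity fields used as rendering and test oracles.

    ``linear_gradient(a, b, c)``: ``a + b*x + c*y``.
    ``gaussian_blob_sum(blobs, background)``: background plus a sum of
    :class:`GaussianBlob`.
    ``ring(center, radius, width, amplitude, background)``: a Gaussian ridge
    at distance ``radius`` from ``center``.
    All return a callable ``(x, y) -> intensity``; values are *not* clipped.
    """
    if name == "linear_gradient":
        a, b, c = params["a"], params["b"], params["c"]
        return lambda x, y: a + b * np.asarray(x, float) + c * np.asarray(y, float)
    if name == "gaussian_blob_sum":
        blobs = tuple(params["blobs"])
        background = params.get("background", 0.0)
        def f(x, y):
            out = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                          float(background))
            for blob in blobs:
                out = out + blob(x, y)
            return out
        return f
    if name == "ring":
        cx, cy = params["center"]
        radius = params["radius"]
        width = params["width"]
        amplitude = params["amplitude"]
        background = params.get("background", 0.0)
        def g(x, y):
            r = np.hypot(np.asarray(x, float) - cx, np.asarray(y, float) - cy)
            return background + amplitude * np.exp(
                -((r - radius) ** 2) / (2.0 * width ** 2))
        return g
    raise ValueError(f"unknown analytic field {name!r}")


@dataclass(frozen=True)
class FinGeometry:
    """Closed-form geometry of the template fin in template pixel coords."""

    x0: float = 30.0
    yc: float = 64.0
    a: float = 100.0
    b: float = 45.0
    band_halfwidth: float = 5.0
    band_end_inset: float = 10.0

    def inside_fin(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= self.x0) & (((x - self.x0) / self.a) ** 2
                                 + ((y - self.yc) / self.b) ** 2 <= 1.0)

    def inside_band(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (np.abs(y - self.yc) <= self.band_halfwidth) \
            & (x >= self.x0) & (x <= self.x0 + self.a - self.band_end_inset)

    def arc_point(self, t, upper: bool):
        sign = -1.0 if upper else 1.0
        t = np.asarray(t, float)
        return np.column_stack([self.x0 + self.a * np.sin(t),
                                self.yc + sign * self.b * np.cos(t)])

    def outline_distance(self, x, y):
        """Approximate distance to the outline (arcs + left edge + band edges).

        Used to define the boundary band when scoring variance maps; exact
        elliptical distance is unnecessary — a scaled implicit-function
        distance is accurate to well under a pixel near the curve.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        u = (x - self.x0) / self.a
        v = (y - self.yc) / self.b
        r = np.sqrt(u ** 2 + v ** 2)
        grad = np.sqrt((u / self.a) ** 2 + (v / self.b) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_ellipse = np.where(grad > 0, np.abs(r ** 2 - 1.0) / (2 * grad),
                                 np.inf)
        d_band = np.abs(np.abs(y - self.yc) - self.band_halfwidth)
        in_band_x = (x >= self.x0) & (x <= self.x0 + self.a
                                      - self.band_end_inset)
        d_band = np.where(in_band_x, d_band, np.inf)
        return np.minimum(d_ellipse, d_band)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic multi-group sample.

    Defaults mirror the emulated study design: three age-like groups of
    sizes 7/8/5 with graded shape and texture effects.  All randomness
    derives from ``seed``; identical specs give bit-identical samples.
    """

    group_sizes: tuple = (7, 8, 5)
    shape_effect_scales: tuple = (0.0, 1.0, 1.6)
    texture_blob_amplitudes: tuple = (0.0, -0.12, -0.22)
    texture_blob_center: tuple = (70.0, 40.0)
    texture_blob_sigma: float = 12.0
    landmark_noise_sd: float = 0.4
    tangential_jitter: float = 2.5
    affine_wobble_sd: float = 0.015
    variance_regions: tuple = (
        GaussianBlob((85.0, 86.0), 10.0, 1.0),
        GaussianBlob((55.0, 30.0), 8.0, 1.0),
    )
    region_amplitude_sd: float = 0.10
    texture_noise_sd: float = 0.02
    image_size: tuple = (128, 160)
    supersample: int = 4
    n_semis_per_arc: int = 10
    n_semis_notochord: int = 6
    geometry: FinGeometry = field(default_factory=FinGeometry)
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != len(self.shape_effect_scales) or \
                len(self.group_sizes) != len(self.texture_blob_amplitudes):
            raise ValueError("per-group parameter lengths disagree")
        for sd in (self.landmark_noise_sd, self.texture_noise_sd,
                   self.region_amplitude_sd, self.tangential_jitter):
            if sd < 0:
                raise ValueError("noise magnitudes must be non-negative")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_specimens(self) -> int:
        return int(sum(self.group_sizes))


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A spec with all group effects removed (shared shape and texture)."""
    n = len(overrides.get("group_sizes", SyntheticSpec.group_sizes))
    base = dict(shape_effect_scales=(0.0,) * n,
                texture_blob_amplitudes=(0.0,) * n, seed=seed)
    base.update(overrides)
    return SyntheticSpec(**base)


def fin_template(spec: SyntheticSpec) -> LandmarkConfiguration:
    """The template landmark configuration in template pixel coordinates.

    Four anatomical landmarks (fin tip, the two arc origins, midline base)
    plus three open semilandmark curves: upper arc, lower arc, midline band
    axis.
    """
    g = spec.geometry
    anat = np.array([
        [g.x0 + g.a, g.yc],   # 0: fin tip
        [g.x0, g.yc - g.b],   # 1: upper arc origin
        [g.x0, g.yc + g.b],   # 2: lower arc origin
        [g.x0, g.yc],         # 3: midline base
    ])
    t = np.linspace(0.0, np.pi / 2.0, spec.n_semis_per_arc + 2)[1:-1]
    upper = g.arc_point(t, upper=True)
    lower = g.arc_point(t, upper=False)
    xs = np.linspace(g.x0 + 8.0, g.x0 + g.a - g.band_end_inset,
                     spec.n_semis_notochord)
    midline = np.column_stack([xs, np.full_like(xs, g.yc)])
    points = np.vstack([anat, upper, lower, midline])
    k = points.shape[0]
    roles = np.array([ANATOMICAL] * 4 + [SEMILANDMARK] * (k - 4),
                     dtype=object)
    n_arc = spec.n_semis_per_arc
    c_upper = CurveSpec(tuple(range(4, 4 + n_arc)))
    c_lower = CurveSpec(tuple(range(4 + n_arc, 4 + 2 * n_arc)))
    c_mid = CurveSpec(tuple(range(4 + 2 * n_arc, k)))
    return LandmarkConfiguration(points=points, roles=roles,
                                 curves=(c_upper, c_lower, c_mid),
                                 specimen_id="template")


def template_field(spec: SyntheticSpec):
    """The template intensity field: smooth gradient + sharp fin and band.

    Brighter background, a darker fin interior, and a darker midline band —
    sharp boundaries exactly where the semilandmark curves run.
    """
    g = spec.geometry
    def f(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = 0.88 - 0.0006 * x - 0.0003 * y
        out = out - 0.22 * g.inside_fin(x, y)
        out = out - 0.22 * g.inside_band(x, y)
        return out
    return f


def group_displacement(points, alpha: float, geometry: FinGeometry):
    """Smooth, non-affine group shape effect evaluated at landmark positions.

    Elongates the fin along x (quadratic in the normalized chord) and
    narrows it towards the midline, both scaled by ``alpha``.
    """
    pts = np.asarray(points, float)
    u = (pts[:, 0] - geometry.x0) / geometry.a
    v = (pts[:, 1] - geometry.yc) / geometry.b
    dx = 14.0 * u ** 2
    dy = -8.0 * v * np.clip(u, 0.0, None)
    return alpha * np.column_stack([dx, dy])


def _template_tangents(cfg: LandmarkConfiguration) -> np.ndarray:
    from .sliding import _tangents  # local import avoids a cycle
    return _tangents(cfg, cfg.points)


@dataclass
class SyntheticSample:
    """Generated sample plus everything needed to score recovery."""

    images: list
    configs: list
    group_labels: np.ndarray
    ground_truth: dict


def _specimen_field(spec: SyntheticSpec, group: int, region_coeffs):
    base = template_field(spec)
    blob = GaussianBlob(spec.texture_blob_center, spec.texture_blob_sigma,
                        spec.texture_blob_amplitudes[group])
    regions = spec.variance_regions
    def f(x, y):
        out = base(x, y) + blob(x, y)
        for coeff, region in zip(region_coeffs, regions):
            out = out + coeff * region(x, y)
        return out
    return f


def _render(spec: SyntheticSpec, transform: TPSTransform, field,
            rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    ss = spec.supersample
    # Supersampled sample positions covering each unit pixel cell centered
    # on integer coordinates.
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(w)[:, None] + sub[None, :]).ravel()
    ys = (np.arange(h)[:, None] + sub[None, :]).ravel()
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # Invert in chunks to bound the memory of the kernel distance matrices.
    chunks = []
    for start in range(0, pts.shape[0], 65536):
        block = pts[start:start + 65536]
        chunks.append(tps_inverse(transform, block, max_iter=15, tol=1e-6))
    pre = np.vstack(chunks)
    vals = field(pre[:, 0], pre[:, 1]).reshape(h * ss, w * ss)
    img = vals.reshape(h, ss, w, ss).mean(axis=(1, 3))
    if spec.texture_noise_sd > 0:
        img = img + rng.normal(0.0, spec.texture_noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_sample(spec: SyntheticSpec,
                    render_images: bool = True) -> SyntheticSample:
    """Generate landmarks (and images) for every specimen of a spec.

    Per specimen the template landmarks are displaced by the group's smooth
    shape effect and an individual affine wobble; the forward TPS fitted
    through these "true" landmarks deforms the planted intensity field.
    Digitized landmarks are the true ones with tangential semilandmark
    jitter (applied in the template frame, then mapped forward) plus
    isotropic digitization noise.

    With ``render_images=False`` only landmarks and ground truth are
    produced, which makes large replicate studies of the landmark pipeline
    cheap.
    """
    rng = np.random.default_rng(spec.seed)
    template = fin_template(spec)
    tpl_pts = template.points
    centroid = tpl_pts.mean(axis=0)
    tangents = _template_tangents(template)
    semis = template.semilandmark_indices
    images, configs, labels = [], [], []
    truth_specimens = []
    idx = 0
    for group, size in enumerate(spec.group_sizes):
        alpha = spec.shape_effect_scales[group]
        effect = group_displacement(tpl_pts, alpha, spec.geometry)
        for _ in range(size):
            wobble = np.eye(2) + rng.normal(0.0, spec.affine_wobble_sd, (2, 2))
            true_pts = centroid + (tpl_pts + effect - centroid) @ wobble.T
            transform = tps_fit(tpl_pts, true_pts)
            jitter = rng.uniform(-spec.tangential_jitter,
                                 spec.tangential_jitter, semis.size)
            jittered_tpl = tpl_pts.copy()
            jittered_tpl[semis] += jitter[:, None] * tangents
            digitized = tps_apply(transform, jittered_tpl)
            if spec.landmark_noise_sd > 0:
                digitized = digitized + rng.normal(
                    0.0, spec.landmark_noise_sd, digitized.shape)
            region_coeffs = rng.normal(0.0, spec.region_amplitude_sd,
                                       len(spec.variance_regions))
            sid = f"g{group}_s{idx:02d}"
            if render_images:
                field_i = _specimen_field(spec, group, region_coeffs)
                pixels = _render(spec, transform, field_i, rng)
                images.append(SpecimenImage(pixels=pixels, specimen_id=sid))
            configs.append(LandmarkConfiguration(
                points=digitized, roles=template.roles,
                curves=template.curves, specimen_id=sid))
            labels.append(group)
            truth_specimens.append({
                "specimen_id": sid,
                "group": group,
                "true_points": true_pts,
                "transform": transform,
                "tangential_jitter": jitter,
                "region_coeffs": region_coeffs,
            })
            idx += 1
    ground_truth = {
        "template": template,
        "template_points": tpl_pts,
        "shape_effect_scales": tuple(spec.shape_effect_scales),
        "texture_blob_center": tuple(spec.texture_blob_center),
        "texture_blob_sigma": spec.texture_blob_sigma,
        "texture_blob_amplitudes": tuple(spec.texture_blob_amplitudes),
        "variance_regions": spec.variance_regions,
        "specimens": truth_specimens,
    }
    return SyntheticSample(images=images, configs=configs,
                           group_labels=np.asarray(labels),
                           ground_truth=ground_truth)
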