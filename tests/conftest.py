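import numpy as np
import pytest

from gmia import FinGeometry, GaussianBlob, SyntheticSpec, generate_sample


def random_configuration(rng, k=8, spread=10.0, min_dist=0.3):
    """A random non-degenerate point set (rejection-sampled)."""
    while True:
        pts = rng.uniform(0, spread, (k, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < min_dist:
            continue
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] > 1e-3 * s[0]:
            return pts


def random_similarity(rng):
    """Random rotation + uniform scale + translation."""
    th = rng.uniform(0, 2 * np.pi)
    s = rng.uniform(0.5, 2.0)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = rng.uniform(-5, 5, 2)
    return s * R, t


@pytest.fixture(scope="session")
def small_spec():
    """A reduced synthetic spec for fast image-level tests."""
    return SyntheticSpec(group_sizes=(3, 3, 2), image_size=(64, 80),
                         supersample=2, n_semis_per_arc=6,
                         n_semis_notochord=4,
                         geometry=FinGeometry(
                             x0=15.0, yc=32.0, a=50.0, b=22.0,
                             band_halfwidth=3.0, band_end_inset=6.0),
                         texture_blob_center=(35.0, 20.0),
                         texture_blob_sigma=7.0,
                         variance_regions=(
                             GaussianBlob((43.0, 43.0), 5.0, 1.0),
                             GaussianBlob((28.0, 15.0), 4.0, 1.0)),
                         seed=11)


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return generate_sample(small_spec)
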