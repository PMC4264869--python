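"""Thin-plate spline mathematics: interpolation exactness, bending energy,
side conditions, the quadratic-form matrix, grids, and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmia.tps import (DegenerateConfigurationError, bending_energy,
                      bending_energy_matrix, deformation_grid, tps_apply,
                      tps_fit, tps_inverse, tps_kernel)

from _oracles import (dense_bending_energy, dense_bending_energy_matrix,
                      dense_tps_eval, dense_tps_solve)
from conftest import random_configuration, random_similarity

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
DISPLACED = np.array([[0.0, 0.0], [1.0, 0.0], [1.25, 1.25], [0.0, 1.0]])
# Frozen from the dense-system oracle (tests/_oracles.py) before the
# optimized path existed.
SQUARE_ORACLE_BE = 0.04508422002778009
SQUARE_ORACLE_CENTER = np.array([0.5625, 0.5625])


def test_kernel_zero_at_origin_and_symmetric():
    assert tps_kernel(0.0) == 0.0
    assert tps_kernel(1e-15) == 0.0  # guarded region
    r = np.array([0.5, 1.0, 2.0])
    np.testing.assert_allclose(tps_kernel(r), r * r * np.log(r))


def test_identity_fit_is_identity_map():
    rng = np.random.default_rng(0)
    pts = random_configuration(rng, k=7)
    t = tps_fit(pts, pts)
    assert t.bending_energy < 1e-12
    np.testing.assert_allclose(t.affine, np.array([[0, 0], [1, 0], [0, 1]],
                                                  float), atol=1e-9)
    np.testing.assert_allclose(t.weights, 0.0, atol=1e-9)
    probe = rng.uniform(-3, 3, (11, 2))
    np.testing.assert_allclose(tps_apply(t, probe), probe, atol=1e-9)


def test_affine_target_has_zero_bending_energy():
    rng = np.random.default_rng(1)
    pts = random_configuration(rng, k=6)
    th = np.pi / 6
    A = 2.0 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = tps_fit(pts, pts @ A.T + [3.0, -1.0])
    assert t.bending_energy < 1e-10


def test_exact_interpolation_and_side_conditions():
    rng = np.random.default_rng(2)
    for _ in range(20):
        src = random_configuration(rng, k=int(rng.integers(4, 12)))
        tgt = src + rng.normal(0, 0.5, src.shape)
        t = tps_fit(src, tgt)
        diam = np.linalg.norm(src.max(0) - src.min(0))
        assert np.abs(tps_apply(t, src) - tgt).max() < 1e-9 * max(diam, 1.0)
        np.testing.assert_allclose(t.weights.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(src.T @ t.weights, 0.0, atol=1e-8)
        assert t.bending_energy >= 0.0


def test_displaced_square_matches_frozen_oracle():
    t = tps_fit(SQUARE, DISPLACED)
    assert t.bending_energy == pytest.approx(SQUARE_ORACLE_BE, abs=1e-12)
    center = tps_apply(t, np.array([[0.5, 0.5]]))[0]
    np.testing.assert_allclose(center, SQUARE_ORACLE_CENTER, atol=1e-12)
    # and the oracle itself still reproduces both numbers
    w, a, be, _, _ = dense_tps_solve(SQUARE, DISPLACED)
    assert be == pytest.approx(SQUARE_ORACLE_BE, abs=1e-12)
    np.testing.assert_allclose(dense_tps_eval(SQUARE, w, a, [[0.5, 0.5]])[0],
                               SQUARE_ORACLE_CENTER, atol=1e-12)


def test_fit_matches_dense_oracle_on_random_cases():
    rng = np.random.default_rng(3)
    for _ in range(10):
        src = random_configuration(rng, k=int(rng.integers(5, 16)))
        tgt = src + rng.normal(0, 0.4, src.shape)
        t = tps_fit(src, tgt)
        be = dense_bending_energy(src, tgt)
        assert t.bending_energy == pytest.approx(be, abs=1e-8, rel=1e-8)
        probe = rng.uniform(0, 10, (4, 2))
        w, a, _, _, _ = dense_tps_solve(src, tgt)
        np.testing.assert_allclose(tps_apply(t, probe),
                                   dense_tps_eval(src, w, a, probe),
                                   atol=1e-8)


def test_cross_check_against_scipy_rbf():
    from scipy.interpolate import RBFInterpolator

    rng = np.random.default_rng(4)
    src = random_configuration(rng, k=9)
    tgt = src + rng.normal(0, 0.6, src.shape)
    t = tps_fit(src, tgt)
    rbf = RBFInterpolator(src, tgt, kernel="thin_plate_spline")
    probe = rng.uniform(0, 10, (25, 2))
    np.testing.assert_allclose(tps_apply(t, probe), rbf(probe), atol=1e-9)


@pytest.mark.parametrize("bad_target_rows", [3, 5])
def test_count_mismatch_raises(bad_target_rows):
    rng = np.random.default_rng(5)
    src = random_configuration(rng, k=4)
    with pytest.raises(ValueError, match="points"):
        tps_fit(src, rng.uniform(0, 1, (bad_target_rows, 2)))


def test_duplicate_source_points_name_the_offenders():
    src = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    with pytest.raises(DegenerateConfigurationError, match="1 and 2"):
        tps_fit(src, src + 0.1)


def test_collinear_source_raises():
    src = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
    with pytest.raises(DegenerateConfigurationError, match="collinear"):
        tps_fit(src, src + 0.1)


class TestBendingEnergyMatrix:
    def test_symmetric_psd_with_affine_null_space(self):
        rng = np.random.default_rng(6)
        ref = random_configuration(rng, k=8)
        B = bending_energy_matrix(ref)
        np.testing.assert_allclose(B, B.T, atol=1e-12)
        vals = np.linalg.eigvalsh(B)
        assert vals.min() > -1e-8
        # affine targets cost nothing
        affine_target = ref @ rng.normal(size=(2, 2)) + rng.normal(size=2)
        assert bending_energy(B, affine_target) < 1e-8
        for col in (np.ones(8), ref[:, 0], ref[:, 1]):
            assert np.abs(B @ col).max() < 1e-8

    def test_quadratic_form_equals_fit_energy(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ref = random_configuration(rng, k=5)
            tgt = ref + rng.normal(0, 0.5, ref.shape)
            B = bending_energy_matrix(ref)
            assert bending_energy(B, tgt) == pytest.approx(
                tps_fit(ref, tgt).bending_energy, abs=1e-8)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(8)
        ref = random_configuration(rng, k=6)
        np.testing.assert_allclose(bending_energy_matrix(ref),
                                   dense_bending_energy_matrix(ref),
                                   atol=1e-8)


class TestDeformationGrid:
    def test_identity_grid_is_regular(self):
        rng = np.random.default_rng(9)
        shape = random_configuration(rng, k=6)
        rows, cols = deformation_grid(shape, shape, 5, 7, margin=0.1)
        assert len(rows) == 5 and len(cols) == 7
        xs = np.unique(np.round(np.vstack(rows)[:, 0], 9))
        assert len(xs) == 7  # columns stay on 7 distinct x positions
        for r in rows:
            assert np.ptp(r[:, 1]) < 1e-9  # horizontal lines stay flat

    def test_translation_shifts_grid_rigidly(self):
        rng = np.random.default_rng(10)
        shape = random_configuration(rng, k=5)
        rows0, _ = deformation_grid(shape, shape, 4, 4)
        rows1, _ = deformation_grid(shape, shape + [2.0, -3.0], 4, 4)
        for a, b in zip(rows0, rows1):
            np.testing.assert_allclose(b, a + [2.0, -3.0], atol=1e-8)

    def test_grid_vertices_equal_tps_apply(self):
        rows, cols = deformation_grid(SQUARE, DISPLACED, 3, 3, margin=0.0)
        t = tps_fit(SQUARE, DISPLACED)
        xs = np.linspace(0, 1, 3)
        gx, gy = np.meshgrid(xs, xs)
        expected = tps_apply(t, np.column_stack([gx.ravel(), gy.ravel()]))
        np.testing.assert_allclose(np.vstack(rows), expected, atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_affine_invariance_property(seed):
    """Bending energy of any nonsingular affine image of the source is zero."""
    rng = np.random.default_rng(seed)
    src = random_configuration(rng, k=int(rng.integers(4, 10)))
    while True:
        A = rng.normal(size=(2, 2))
        if abs(np.linalg.det(A)) > 0.1:
            break
    t = tps_fit(src, src @ A.T + rng.normal(size=2))
    assert t.bending_energy < 1e-10


def test_inverse_round_trip():
    rng = np.random.default_rng(11)
    src = random_configuration(rng, k=8, spread=100.0)
    tgt = src + rng.normal(0, 4.0, src.shape)
    t = tps_fit(src, tgt)
    probe = rng.uniform(10, 90, (50, 2))
    pre = tps_inverse(t, probe, tol=1e-10)
    np.testing.assert_allclose(tps_apply(t, pre), probe, atol=1e-8)
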