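import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

import histostrain as hs
from histostrain.strain import (
    FlatTextureError,
    VolumePair,
    WarpParameters,
    estimate_warp,
    green_lagrange,
    green_lagrange_principal,
    strain_field_from_volumes,
    warp_to_deformation_gradient,
)


class TestWarpLayout:
    def test_zero_parameters_give_identity(self):
        F = warp_to_deformation_gradient(WarpParameters.zeros())
        np.testing.assert_array_equal(F, np.eye(3))

    def test_p4_fills_first_row_second_column(self):
        p = np.zeros(12)
        p[3] = 0.05  # p4
        F = warp_to_deformation_gradient(WarpParameters(p))
        assert F[0, 1] == 0.05
        np.testing.assert_array_equal(np.diag(F), np.ones(3))

    def test_p1_stretches_first_axis(self):
        p = np.zeros(12)
        p[0] = 0.1
        F = warp_to_deformation_gradient(WarpParameters(p))
        np.testing.assert_array_equal(F, np.diag([1.1, 1.0, 1.0]))

    def test_column_wise_layout(self):
        F = warp_to_deformation_gradient(WarpParameters(np.arange(1.0, 13.0)))
        expected = np.eye(3) + np.array([[1, 4, 7], [2, 5, 8], [3, 6, 9]], dtype=float)
        np.testing.assert_array_equal(F, expected)


class TestGreenLagrangePrincipal:
    def test_identity_gives_zero_strain(self):
        e1, _, _ = green_lagrange_principal(np.eye(3))
        assert e1 == 0.0

    def test_uniaxial_stretch_closed_form(self):
        e1, direction, _ = green_lagrange_principal(np.diag([1.1, 1.0, 1.0]))
        assert e1 == pytest.approx((1.1**2 - 1.0) / 2.0, abs=1e-15)
        assert abs(direction[0]) == pytest.approx(1.0)

    def test_simple_shear_matches_eigensolver_oracle(self):
        F = np.array([[1.0, 0.2], [0.0, 1.0]])
        e1, _, w = green_lagrange_principal(F)
        oracle = np.max(np.linalg.eigvalsh(0.5 * (F.T @ F - np.eye(2))))
        assert e1 == pytest.approx(oracle, abs=1e-14)
        # orthonormal principal directions
        _, v = np.linalg.eigh(green_lagrange(F))
        np.testing.assert_allclose(v.T @ v, np.eye(2), atol=1e-14)

    def test_pure_rotation_has_zero_strain(self):
        th = 0.3
        R = np.array(
            [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
        )
        e1, _, _ = green_lagrange_principal(R)
        assert abs(e1) < 1e-9

    def test_non_physical_gradient_rejected(self):
        with pytest.raises(hs.strain.NonPhysicalWarpError):
            green_lagrange_principal(np.diag([-1.0, 1.0, 1.0]))


WINDOW = [(8, 24), (8, 24), (8, 24)]


class TestEstimateWarp:
    def test_identical_volumes_give_zero_warp(self):
        pair = hs.generate_volume_pair((32, 32, 32), WarpParameters.zeros(), seed=3)
        est = estimate_warp(pair, WINDOW)
        assert np.abs(est.parameters.p).max() < 1e-6

    def test_known_warp_recovered(self):
        p_true = WarpParameters(
            np.array([0.05, 0.01, 0.0, -0.02, -0.03, 0.01, 0.0, 0.02, 0.04, 0.5, -0.3, 0.2])
        )
        pair = hs.generate_volume_pair((32, 32, 32), p_true, seed=3)
        est = estimate_warp(pair, WINDOW)
        assert est.converged
        assert np.abs(est.parameters.p - p_true.p).max() < 1e-3

    def test_noisy_strain_recovery_over_seeds(self):
        p_true = WarpParameters(
            np.array([0.06, 0.02, -0.01, 0.03, -0.04, 0.0, 0.01, 0.0, 0.05, 0.8, -0.5, 0.3])
        )
        e1_true, _, _ = green_lagrange_principal(warp_to_deformation_gradient(p_true))
        for seed in range(20):
            pair = hs.generate_volume_pair((32, 32, 32), p_true, noise_sd=0.01, seed=seed)
            est = estimate_warp(pair, WINDOW)
            e1, _, _ = green_lagrange_principal(warp_to_deformation_gradient(est.parameters))
            assert abs(e1 - e1_true) < 0.005

    def test_flat_window_rejected(self):
        flat = VolumePair(np.zeros((32, 32, 32)), np.zeros((32, 32, 32)))
        with pytest.raises(FlatTextureError):
            estimate_warp(flat, WINDOW)

    def test_small_window_rejected(self):
        pair = hs.generate_volume_pair((32, 32, 32), WarpParameters.zeros(), seed=1)
        with pytest.raises(ValueError):
            estimate_warp(pair, [(8, 14), (8, 24), (8, 24)])

    def test_objectivity_under_coordinate_rotation(self):
        # axis permutation (a rotation) of both volumes leaves E1 unchanged
        p_true = WarpParameters(np.r_[0.05, 0.0, 0.0, 0.0, -0.03, 0.0, 0.0, 0.0, 0.02, 0, 0, 0])
        pair = hs.generate_volume_pair((32, 32, 32), p_true, seed=8)
        rotated = VolumePair(
            np.rot90(pair.reference, axes=(0, 1)).copy(),
            np.rot90(pair.target, axes=(0, 1)).copy(),
            pair.voxel_size_um,
        )
        e1 = green_lagrange_principal(
            warp_to_deformation_gradient(estimate_warp(pair, WINDOW).parameters)
        )[0]
        e1_rot = green_lagrange_principal(
            warp_to_deformation_gradient(estimate_warp(rotated, WINDOW).parameters)
        )[0]
        assert abs(e1 - e1_rot) < 1e-6


class TestStrainFieldFromVolumes:
    def test_zero_deformation_gives_zero_field(self):
        pair = hs.generate_volume_pair((32, 32, 32), WarpParameters.zeros(), seed=2)
        field = strain_field_from_volumes(pair, window_size=16, overlap=0.5)
        assert np.abs(field.values[field.mask]).max() < 1e-4

    def test_global_affine_gives_uniform_field(self):
        p_true = WarpParameters(
            np.array([0.05, 0.01, 0.0, -0.02, -0.03, 0.01, 0.0, 0.02, 0.04, 0.0, 0.0, 0.0])
        )
        pair = hs.generate_volume_pair((32, 32, 32), p_true, seed=3)
        field = strain_field_from_volumes(pair, window_size=16, overlap=0.5)
        e1_true, _, _ = green_lagrange_principal(warp_to_deformation_gradient(p_true))
        assert np.abs(field.values[field.mask] - e1_true).max() < 1e-3

    def test_two_zone_warp_recovers_both_stretches(self):
        rng = np.random.default_rng(9)
        shape = (64, 32, 32)
        base = gaussian_filter(rng.standard_normal(shape), 1.5)
        base = (base - base.mean()) / base.std()
        a, b, x0 = 1.05, 1.02, 31.5
        grid = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"), axis=0
        )
        x = grid[0]
        xw = np.where(x < x0, x0 + a * (x - x0), x0 + b * (x - x0))
        coords = np.stack([xw, grid[1], grid[2]], axis=0).reshape(3, -1)
        ref = map_coordinates(base, coords, order=1, mode="nearest").reshape(shape)
        field = strain_field_from_volumes(VolumePair(ref, base, 40.0), window_size=16)
        centers = field.origin_um[0] / 40.0 + (np.arange(field.values.shape[0]) + 0.5) * (
            field.voxel_size_um / 40.0
        )
        left = np.where(field.mask[centers < x0 - 8], field.values[centers < x0 - 8], np.nan)
        right = np.where(field.mask[centers > x0 + 8], field.values[centers > x0 + 8], np.nan)
        assert abs(np.nanmedian(left) - (a * a - 1) / 2) < 0.005
        assert abs(np.nanmedian(right) - (b * b - 1) / 2) < 0.005

    def test_all_windows_failing_raises(self):
        flat = VolumePair(np.zeros((32, 32, 32)), np.zeros((32, 32, 32)))
        with pytest.raises(ValueError):
            strain_field_from_volumes(flat, window_size=16)
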