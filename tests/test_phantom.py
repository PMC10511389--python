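import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import correlate

import histostrain as hs
from histostrain.phantom import PhantomGeometry, PhantomGeometryError
from histostrain.raster import raster_grid, rasterize_polygon
from histostrain.strain import WarpParameters


class TestCrossSectionPhantom:
    def test_same_seed_is_bit_identical(self):
        a = hs.generate_cross_section_phantom(seed=7)
        b = hs.generate_cross_section_phantom(seed=7)
        assert np.array_equal(a.deformed_lumen.points, b.deformed_lumen.points)
        assert np.array_equal(a.strain_field.values, b.strain_field.values)
        for lab in a.undeformed_regions.regions:
            assert np.array_equal(
                a.undeformed_regions.regions[lab].points,
                b.undeformed_regions.regions[lab].points,
            )

    def test_boundary_displacement_reproduces_deformed_contours(self, phantom_ref):
        u = phantom_ref.ground_truth_displacement
        regs = phantom_ref.undeformed_regions
        assert (
            np.abs(u.map_points(regs.lumen.points) - phantom_ref.deformed_lumen.points).max()
            < 1e-9
        )
        assert (
            np.abs(u.map_points(regs.outer.points) - phantom_ref.deformed_outer.points).max()
            < 1e-9
        )

    def test_requested_region_area_proportion(self):
        geometry = PhantomGeometry(
            region_proportions={"A1": 0.2, "A2": 0.15, "A3": 0.15, "A4": 0.2, "A5": 0.3}
        )
        ph = hs.generate_cross_section_phantom(geometry, seed=9)
        regs = ph.undeformed_regions
        origin, shape = raster_grid([regs.outer.points], 1.0)
        a5 = rasterize_polygon(regs.regions["A5"].points, origin, shape, 1.0).sum()
        wall = (
            rasterize_polygon(regs.outer.points, origin, shape, 1.0).sum()
            - rasterize_polygon(regs.lumen.points, origin, shape, 1.0).sum()
        )
        assert abs(a5 / wall - 0.3) < 0.02

    def test_regions_tile_wall_without_overlap(self, phantom_ref):
        regs = phantom_ref.undeformed_regions
        origin, shape = raster_grid([regs.outer.points], 2.0)
        masks = {
            l: rasterize_polygon(c.points, origin, shape, 2.0)
            for l, c in regs.regions.items()
        }
        labels = sorted(masks)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                overlap = (masks[a] & masks[b]).sum()
                assert overlap < 0.005 * min(masks[a].sum(), masks[b].sum())
        union = np.zeros(shape, dtype=bool)
        total = 0
        for m in masks.values():
            union |= m
            total += m.sum()
        wall = regs.wall_area()
        assert abs(union.sum() * 4.0 - wall) / wall < 0.01

    def test_zero_amplitude_gives_identity_deformation(self):
        ph = hs.generate_cross_section_phantom(
            PhantomGeometry(deformation_amplitude=0.0), seed=2
        )
        assert np.array_equal(ph.deformed_lumen.points, ph.undeformed_regions.lumen.points)
        assert np.array_equal(ph.deformed_outer.points, ph.undeformed_regions.outer.points)

    def test_lumen_strictly_inside_outer(self, phantom_ref):
        regs = phantom_ref.undeformed_regions
        r_l = np.hypot(*regs.lumen.points.T)
        r_o = np.hypot(*regs.outer.points.T)
        assert r_l.max() < r_o.min()

    def test_wall_collapse_rejected_with_parameter_name(self):
        with pytest.raises(PhantomGeometryError, match="deformation_amplitude"):
            hs.generate_cross_section_phantom(
                PhantomGeometry(deformation_amplitude=0.9, wall_thickness_um=20.0), seed=0
            )

    def test_invalid_proportions_rejected(self):
        with pytest.raises(PhantomGeometryError):
            hs.generate_cross_section_phantom(
                PhantomGeometry(region_proportions={"A5": 0.3}), seed=0
            )

    def test_displacement_field_is_smooth_in_wall(self, phantom_ref):
        # bounded finite-difference second derivatives inside the wall
        u = phantom_ref.ground_truth_displacement
        r = 575.0
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = r * np.column_stack([np.cos(th), np.sin(th)])
        disp = u.displacement(pts)
        d2 = np.diff(disp, 2, axis=0) / (r * (th[1] - th[0])) ** 2
        assert np.abs(d2).max() < 0.01  # 1/µm, gentle curvature


class TestStrainFieldGenerator:
    def test_zero_noise_gives_exact_region_levels(self, phantom_ref):
        regs = phantom_ref.deformed_regions()
        levels = {l: 0.02 * (i + 1) for i, l in enumerate(sorted(regs.regions))}
        field = hs.generate_strain_field(regs, levels, noise_sd=0.0, seed=0)
        grouped = hs.group_strains(field, regs)
        for lab, vals in grouped.samples.items():
            assert np.all(vals == levels[lab])

    def test_region_means_recovered_within_two_standard_errors(self, phantom_ref):
        grouped = hs.group_strains(phantom_ref.strain_field, phantom_ref.deformed_regions())
        for lab, vals in grouped.samples.items():
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            # clipping at zero biases upward slightly; two SE still covers it
            assert abs(vals.mean() - phantom_ref.region_levels[lab]) < max(2 * se, 0.005)

    def test_same_seed_identical_field(self, phantom_ref):
        regs = phantom_ref.deformed_regions()
        f1 = hs.generate_strain_field(regs, phantom_ref.region_levels, seed=5)
        f2 = hs.generate_strain_field(regs, phantom_ref.region_levels, seed=5)
        assert np.array_equal(f1.values, f2.values)

    def test_empty_region_set_rejected(self, phantom_ref):
        regs = phantom_ref.deformed_regions()
        empty = hs.TissueRegionSet(lumen=regs.lumen, outer=regs.outer, regions={})
        with pytest.raises(ValueError):
            hs.generate_strain_field(empty, {}, seed=0)


class TestVolumePairGenerator:
    def test_zero_warp_zero_noise_identity(self):
        pair = hs.generate_volume_pair((16, 16, 16), WarpParameters.zeros(), seed=3)
        assert np.array_equal(pair.reference, pair.target)

    def test_pure_translation_shows_in_cross_correlation(self):
        p = WarpParameters(np.r_[np.zeros(9), 2.0, 0.0, 0.0])
        pair = hs.generate_volume_pair((32, 32, 32), p, seed=5)
        c = correlate(
            pair.target - pair.target.mean(),
            pair.reference - pair.reference.mean(),
            mode="same",
        )
        offset = np.array(np.unravel_index(np.argmax(c), c.shape)) - np.array(c.shape) // 2
        assert abs(offset[0]) == 2 and offset[1] == 0 and offset[2] == 0

    def test_same_seed_identical_pair(self):
        p = WarpParameters(np.r_[0.05, np.zeros(11)])
        a = hs.generate_volume_pair((16, 16, 16), p, noise_sd=0.01, seed=11)
        b = hs.generate_volume_pair((16, 16, 16), p, noise_sd=0.01, seed=11)
        assert np.array_equal(a.reference, b.reference)

    def test_out_of_domain_warp_rejected(self):
        p = WarpParameters(np.r_[np.zeros(9), 50.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            hs.generate_volume_pair((16, 16, 16), p, seed=0)

    def test_small_shapes_rejected(self):
        with pytest.raises(ValueError):
            hs.generate_volume_pair((8, 16, 16), WarpParameters.zeros(), seed=0)


class TestGroupDatasetGenerator:
    def test_aaa_samples_are_right_skewed(self):
        aaa, _ = hs.generate_group_dataset(1, 1, seed=3, samples_per_specimen=10000)
        assert sps.skew(aaa.specimens[0], bias=False) > 0

    def test_non_aaa_samples_are_left_skewed(self):
        _, non = hs.generate_group_dataset(1, 1, seed=3, samples_per_specimen=10000)
        assert sps.skew(non.specimens[0], bias=False) < 0

    def test_same_seed_identical_datasets(self):
        a1, n1 = hs.generate_group_dataset(3, 2, seed=8)
        a2, n2 = hs.generate_group_dataset(3, 2, seed=8)
        for x, y in zip(a1.specimens + n1.specimens, a2.specimens + n2.specimens):
            assert np.array_equal(x, y)

    def test_samples_physical(self):
        aaa, non = hs.generate_group_dataset(2, 2, seed=1)
        for s in aaa.specimens + non.specimens:
            assert np.all(np.isfinite(s)) and np.all(s > -0.5)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            hs.generate_group_dataset(0, 3, seed=0)
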