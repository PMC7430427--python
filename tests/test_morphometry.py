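"""Planar sections, Feret calipers, 3D measures and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mh3d import (EllipseSection, HoleMask, VoxelSpacing, classify_ivts,
                  extract_sections, feret_diameters, find_minimum_area,
                  generate_phantom, heights, hole_volume, measure_hole,
                  surface_area, truncated_cone_volume)
from mh3d.morphometry import (axial_mean_deg, boundary_sections, centre_line,
                              principal_axis_angle)
from mh3d.oct_io import SurfaceMap

from conftest import TINY, angle_diff_deg, tiny_cylinder_spec, tiny_hourglass_spec


def brute_force_feret(points: np.ndarray, step_deg: float = 0.1):
    """Directional-extent sweep oracle for Feret diameters."""
    thetas = np.arange(0.0, 180.0, step_deg)
    d = np.stack([np.cos(np.radians(thetas)), np.sin(np.radians(thetas))])
    proj = points @ d  # (n_points, n_angles)
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(extents.min()), float(extents.max())


def raster_ellipse(a, b, theta_deg, px, pz, pad=30.0):
    n_x = int(2 * (max(a, b) + pad) / px)
    n_z = int(2 * (max(a, b) + pad) / pz)
    x = (np.arange(n_x) - n_x / 2) * px
    z = (np.arange(n_z) - n_z / 2) * pz
    X, Z = np.meshgrid(x, z, indexing="ij")
    t = math.radians(theta_deg)
    u = X * math.cos(t) + Z * math.sin(t)
    w = -X * math.sin(t) + Z * math.cos(t)
    return (u / a) ** 2 + (w / b) ** 2 <= 1.0


class TestFeret:
    def test_axis_aligned_rectangle(self):
        region = np.ones((20, 10), bool)  # 200 x 100 um at 10 um pixels
        fmin, fmax, amin, amax = feret_diameters(region, (10.0, 10.0))
        assert fmin == pytest.approx(100.0)
        assert fmax == pytest.approx(math.hypot(200.0, 100.0))
        assert amin == pytest.approx(90.0)

    def test_digitised_circle(self):
        region = raster_ellipse(50.0, 50.0, 0.0, 2.0, 2.0)
        fmin, fmax, _, _ = feret_diameters(region, (2.0, 2.0))
        assert fmin == pytest.approx(100.0, abs=2.5)
        assert fmax == pytest.approx(100.0, abs=3.5)

    def test_rotated_ellipse(self):
        region = raster_ellipse(200.0, 150.0, 30.0, 2.0, 2.0)
        fmin, fmax, amin, amax = feret_diameters(region, (2.0, 2.0))
        assert fmax == pytest.approx(400.0, abs=4.0)  # within 2 px
        assert fmin == pytest.approx(300.0, abs=4.0)
        assert angle_diff_deg(amax, 30.0) < 4.0
        assert angle_diff_deg(amin, 120.0) < 4.0

    def test_single_pixel_has_pixel_extent(self):
        region = np.zeros((5, 5), bool)
        region[2, 2] = True
        fmin, fmax, _, _ = feret_diameters(region, (5.47, 30.0))
        assert fmin == pytest.approx(5.47)
        assert fmax == pytest.approx(math.hypot(5.47, 30.0))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            feret_diameters(np.zeros((4, 4), bool), (1.0, 1.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle_on_convex_polygons(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = rng.uniform(30.0, 300.0, n)
        pts = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        fmin, fmax, _, _ = feret_diameters(None, (1.0, 1.0), points=pts)
        omin, omax = brute_force_feret(pts)
        assert fmax == pytest.approx(omax, rel=5e-3)
        assert fmin == pytest.approx(omin, rel=5e-3, abs=1e-9)

    def test_principal_axis_matches_ellipse_orientation(self):
        region = raster_ellipse(200.0, 150.0, 57.0, 5.0, 5.0)
        assert angle_diff_deg(
            principal_axis_angle(region, (5.0, 5.0)), 57.0) < 1.0


class TestSections:
    @pytest.fixture(scope="module")
    @staticmethod
    def cylinder_truth():
        spec = tiny_cylinder_spec()
        _, mask, truth = generate_phantom(spec)
        return spec, mask, truth

    def test_cylinder_sections(self, cylinder_truth):
        spec, mask, truth = cylinder_truth
        secs = extract_sections(mask, spec.rpe_depth_um)
        r = 150.0
        for s in secs:
            assert s.area_um2 == pytest.approx(math.pi * r * r, rel=0.03)
            assert abs(s.feret_max_um - 300.0) <= 2 * spec.spacing.dx + 1
            assert abs(s.feret_min_um - 300.0) <= 2 * spec.spacing.dz + 1

    def test_single_voxel_mask(self):
        sp = VoxelSpacing(5.47, 3.87, 30.0)
        vox = np.zeros((8, 8, 4), bool)
        vox[3, 2, 1] = True
        secs = extract_sections(HoleMask(vox, sp), rpe=2 * 3.87)
        assert len(secs) == 1
        assert secs[0].area_um2 == pytest.approx(5.47 * 30.0)

    def test_largest_component_wins(self):
        sp = VoxelSpacing(10.0, 10.0, 10.0)
        vox = np.zeros((20, 3, 20), bool)
        vox[2:10, 1, 2:10] = True     # 64 px blob
        vox[14:17, 1, 14:17] = True   # 9 px blob
        secs = extract_sections(HoleMask(vox, sp), rpe=10.0)
        assert secs[0].n_pixels == 64

    def test_empty_mask_rejected(self):
        sp = VoxelSpacing(1, 1, 1)
        with pytest.raises(ValueError):
            extract_sections(HoleMask(np.zeros((4, 4, 4), bool), sp), 1.0)


class TestMinimumArea:
    def test_cylinder_tie_breaks_to_lowest(self, tiny_cylinder):
        spec, _, mask, truth = (tiny_cylinder[0], None, tiny_cylinder[2],
                                tiny_cylinder[3])
        secs = extract_sections(mask, spec.rpe_depth_um)
        H = truth.hole_height_um
        ma = find_minimum_area(secs, H)
        in_band = [s for s in secs if 0.2 * H <= s.height_um <= 0.9 * H]
        assert ma.height_um == min(s.height_um for s in in_band)

    def test_hourglass_returns_waist(self, tiny_hourglass):
        spec, _, mask, truth = (tiny_hourglass[0], None, tiny_hourglass[2],
                                tiny_hourglass[3])
        secs = extract_sections(mask, spec.rpe_depth_um)
        ma = find_minimum_area(secs, truth.hole_height_um)
        assert ma.height_um == pytest.approx(truth.ma_height_um,
                                             abs=spec.spacing.dy)
        assert ma.area_um2 == pytest.approx(truth.ma_area_um2, rel=0.05)

    def test_upward_tapering_clipped_at_90pct(self):
        # widest at base, narrowest at top: minimum clips to the 90% bound
        spec = tiny_cylinder_spec()
        spec = tiny_hourglass_spec()
        kw = dict(TINY, base=EllipseSection(200.0, 200.0),
                  waist=EllipseSection(150.0, 150.0),
                  top=EllipseSection(100.0, 100.0), waist_fraction=0.5)
        from mh3d import PhantomSpec

        spec = PhantomSpec(**kw)
        _, mask, truth = generate_phantom(spec)
        secs = extract_sections(mask, spec.rpe_depth_um)
        ma = find_minimum_area(secs, truth.hole_height_um)
        assert ma.height_um >= 0.9 * truth.hole_height_um - spec.spacing.dy

    def test_empty_band_rejected(self):
        sp = VoxelSpacing(1, 1, 1)
        vox = np.zeros((6, 6, 6), bool)
        vox[2:4, 5, 2:4] = True
        secs = extract_sections(HoleMask(vox, sp), rpe=5.0)
        with pytest.raises(ValueError, match="band"):
            find_minimum_area(secs, hole_height_um=100.0)


class TestBoundariesAndHeights:
    def test_cylinder_top_equals_base(self, tiny_cylinder):
        spec, _, mask, _ = (tiny_cylinder[0], None, tiny_cylinder[2], None)
        base, top, full = boundary_sections(mask, spec.rpe_depth_um)
        assert full
        assert top.area_um2 == pytest.approx(base.area_um2, rel=0.02)

    def test_hourglass_base_diameters(self, tiny_hourglass):
        spec, _, mask, truth = (tiny_hourglass[0], None, tiny_hourglass[2],
                                tiny_hourglass[3])
        base, _, _ = boundary_sections(mask, spec.rpe_depth_um)
        tol = max(2 * spec.spacing.dx, 2 * spec.spacing.dz)
        assert abs(base.feret_max_um - truth.ba_max_um) <= tol
        assert abs(base.feret_min_um - truth.ba_min_um) <= tol

    def test_not_full_thickness_is_flagged(self):
        sp = VoxelSpacing(10.0, 10.0, 10.0)
        vox = np.zeros((20, 12, 20), bool)
        vox[5:15, 2:6, 5:15] = True  # stops 5 slices above the "RPE" at y=110
        with pytest.warns(UserWarning, match="full thickness"):
            _, _, full = boundary_sections(HoleMask(vox, sp), rpe=110.0)
        assert not full

    def test_phantom_heights(self, tiny_cylinder):
        spec, _, mask, truth = (tiny_cylinder[0], None, tiny_cylinder[2],
                                tiny_cylinder[3])
        ilm = SurfaceMap(np.full((spec.nx, spec.nz), spec.ilm_depth_um),
                         "ILM", spec.spacing)
        hole_h, retinal_h = heights(mask, spec.rpe_depth_um, ilm)
        assert hole_h == pytest.approx(truth.hole_height_um,
                                       abs=spec.spacing.dy)
        assert retinal_h == pytest.approx(truth.hole_height_um,
                                          abs=spec.spacing.dy)

    def test_single_voxel_height(self):
        sp = VoxelSpacing(5.0, 4.0, 30.0)
        vox = np.zeros((6, 10, 6), bool)
        vox[3, 8, 3] = True
        ilm = SurfaceMap(np.full((6, 6), 4.0), "ILM", sp)
        hole_h, _ = heights(HoleMask(vox, sp), rpe=9 * 4.0, ilm=ilm)
        assert hole_h == pytest.approx(4.0)


class TestSurfaceAreaAndVolume:
    SP5 = VoxelSpacing(5.0, 5.0, 5.0)

    @staticmethod
    def _grid(n=100):
        c = (n // 2) * 5.0
        ax = np.arange(n) * 5.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        return X - c, Y - c, Z - c

    def test_cube_surface(self):
        X, Y, Z = self._grid(40)
        side = 21 * 5.0  # 21 voxels across
        m = (np.abs(X) <= 50) & (np.abs(Y) <= 50) & (np.abs(Z) <= 50)
        got = surface_area(HoleMask(m, self.SP5))
        assert got == pytest.approx(6 * side ** 2, rel=0.05)

    def test_cylinder_surface_and_volume(self):
        X, Y, Z = self._grid(100)
        m = (X ** 2 + Z ** 2 <= 200.0 ** 2) & (np.abs(Y) <= 150.0)
        h = int((np.abs(np.arange(100) * 5.0 - 250.0) <= 150).sum()) * 5.0
        mask = HoleMask(m, self.SP5)
        assert surface_area(mask) == pytest.approx(
            2 * math.pi * 200 * (h + 200), rel=0.05)
        assert hole_volume(mask) == pytest.approx(
            math.pi * 200 ** 2 * h, rel=0.02)

    def test_single_voxel_volume(self):
        sp = VoxelSpacing(5.47, 3.87, 30.0)
        vox = np.zeros((4, 4, 4), bool)
        vox[1, 1, 1] = True
        assert hole_volume(HoleMask(vox, sp)) == pytest.approx(635.1, abs=0.1)

    def test_empty_volume_is_zero(self):
        sp = VoxelSpacing(1, 1, 1)
        assert hole_volume(HoleMask(np.zeros((4, 4, 4), bool), sp)) == 0.0
        with pytest.raises(ValueError):
            surface_area(HoleMask(np.zeros((4, 4, 4), bool), sp))


class TestCentreLine:
    def test_vertical_cylinder_aligned(self, tiny_cylinder):
        spec, _, mask, _ = (tiny_cylinder[0], None, tiny_cylinder[2], None)
        _, mis = centre_line(mask, spec.rpe_depth_um)
        assert mis <= spec.spacing.dx

    def test_sheared_cylinder_misalignment(self):
        spec = tiny_cylinder_spec(r_um=120.0, tilt_x_um=138.6)  # 240*tan(30)
        _, mask, truth = generate_phantom(spec)
        _, mis = centre_line(mask, spec.rpe_depth_um)
        assert mis == pytest.approx(truth.centre_misalignment_um,
                                    abs=2 * spec.spacing.dx)

    def test_pure_z_shear_has_no_x_component(self):
        spec = tiny_cylinder_spec(r_um=120.0, tilt_z_um=100.0)
        _, mask, _ = generate_phantom(spec)
        centres, _ = centre_line(mask, spec.rpe_depth_um)
        cx = [c[1] for c in centres]
        assert max(cx) - min(cx) <= spec.spacing.dx


class TestClassification:
    @pytest.mark.parametrize("d,cls", [(240.0, "small"), (400.0, "medium"),
                                       (401.0, "large"), (250.0, "small"),
                                       (250.1, "medium")])
    def test_boundaries(self, d, cls):
        assert classify_ivts(d) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_ivts(-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1000),
           st.floats(min_value=0, max_value=1000))
    def test_monotone(self, d1, d2):
        order = {"small": 0, "medium": 1, "large": 2}
        lo, hi = sorted((d1, d2))
        assert order[classify_ivts(lo)] <= order[classify_ivts(hi)]


class TestTruncatedCone:
    def test_cylinder_limit(self):
        assert truncated_cone_volume(400.0, 400.0, 300.0) == pytest.approx(
            math.pi * 300 * 400 ** 2 / 4.0)

    def test_cone_limit(self):
        assert truncated_cone_volume(0.0, 400.0, 300.0) == pytest.approx(
            math.pi * 300 * 400 ** 2 / 12.0)

    def test_matches_slab_quadrature_at_clinical_scale(self):
        # diameters/height on the scale of published cohort means
        mld, bd, h = 357.0, 803.0, 366.0
        hs = np.linspace(0.0, h, 20001)
        d = bd + (mld - bd) * hs / h
        quad = np.trapezoid(math.pi * d ** 2 / 4.0, hs)
        assert truncated_cone_volume(mld, bd, h) == pytest.approx(quad,
                                                                  rel=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            truncated_cone_volume(-1.0, 10.0, 10.0)


class TestAxialMean:
    def test_wraps_around_180(self):
        assert axial_mean_deg([178.0, 2.0]) == pytest.approx(0.0, abs=1e-9)

    def test_weighted(self):
        assert axial_mean_deg([10.0, 30.0], [3.0, 1.0]) == pytest.approx(
            15.0, abs=0.5)


class TestFullReport:
    def test_report_invariants_and_consistency(self, tiny_hourglass):
        spec, _, mask, truth = (tiny_hourglass[0], None, tiny_hourglass[2],
                                tiny_hourglass[3])
        ilm = SurfaceMap(np.full((spec.nx, spec.nz), spec.ilm_depth_um),
                         "ILM", spec.spacing)
        report, sections = measure_hole(mask, spec.rpe_depth_um, ilm)
        assert report.ma_min_um <= report.ma_max_um
        assert report.ba_min_um <= report.ba_max_um
        assert (0.2 * report.hole_height_um <= report.ma_height_um
                <= 0.9 * report.hole_height_um)
        assert report.volume_um3 > 0 and report.surface_area_um2 > 0
        # slice-area integral agrees with the voxel volume
        slab = sum(s.area_um2 for s in sections) * spec.spacing.dy
        assert slab == pytest.approx(report.volume_um3, rel=0.02)
        assert report.ivts_class == classify_ivts(report.ma_min_um)

    def test_waist_asymmetry_recovered(self):
        # elliptical waist: ma_max - ma_min = 2 (a_w - b_w)
        spec = tiny_hourglass_spec()
        _, mask, truth = generate_phantom(spec)
        ilm = SurfaceMap(np.full((spec.nx, spec.nz), spec.ilm_depth_um),
                         "ILM", spec.spacing)
        report, _ = measure_hole(mask, spec.rpe_depth_um, ilm)
        asym = report.ma_max_um - report.ma_min_um
        assert asym >= 0
        expected = 2 * (spec.waist.a_um - spec.waist.b_um)
        assert asym == pytest.approx(expected,
                                     abs=2 * max(spec.spacing.dx,
                                                 spec.spacing.dz))

    def test_mm_conversions(self, tiny_hourglass):
        spec, _, mask, _ = (tiny_hourglass[0], None, tiny_hourglass[2], None)
        ilm = SurfaceMap(np.full((spec.nx, spec.nz), spec.ilm_depth_um),
                         "ILM", spec.spacing)
        report, _ = measure_hole(mask, spec.rpe_depth_um, ilm)
        assert report.surface_area_mm2 == pytest.approx(
            report.surface_area_um2 * 1e-6)
        assert report.volume_1e3_mm3 == pytest.approx(
            report.volume_um3 * 1e-6)
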