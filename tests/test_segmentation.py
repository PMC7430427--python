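"""LGDF level-set evolution and the curvature surface cut."""

import numpy as np
import pytest

from mh3d import (HoleMask, LevelSetField, LevelSetParams, OCTVolume,
                  VoxelSpacing, curvature_surface_cut, dice, evolve_lgdf,
                  generate_phantom, initialize_level_set, multiscale_segment)
from mh3d.oct_io import SurfaceMap, estimate_surfaces
from mh3d.segmentation import SegmentationError, _signed_distance

from conftest import layered_volume, tiny_cylinder_spec


FAST = LevelSetParams(max_iter=60)


def phantom_setup(spec):
    volume, truth_mask, truth = generate_phantom(spec)
    rpe, ilm = estimate_surfaces(volume)
    return volume, truth_mask, truth, rpe, ilm


class TestInitialize:
    def test_seed_overlaps_truth(self):
        volume, truth_mask, *_ , rpe, ilm = (*phantom_setup(tiny_cylinder_spec()),)
        fld = initialize_level_set(volume, rpe, ilm)
        assert dice(fld.interior, truth_mask.voxels) >= 0.8

    def test_seed_inside_band(self):
        volume, _, _, rpe, ilm = phantom_setup(tiny_cylinder_spec())
        fld = initialize_level_set(volume, rpe, ilm)
        yi = np.arange(volume.ny)[None, :, None]
        band = ((yi >= ilm.y_index[:, None, :])
                & (yi <= rpe.y_index[:, None, :]))
        assert not (fld.interior & ~band).any()

    def test_no_hole_raises_empty_seed(self):
        volume = layered_volume()
        rpe, ilm = estimate_surfaces(volume)
        with pytest.raises(SegmentationError, match="seed"):
            initialize_level_set(volume, rpe, ilm)


class TestEvolve:
    def test_recovers_truth_from_eroded_seed(self):
        from scipy import ndimage

        volume, truth_mask, _, rpe, ilm = phantom_setup(tiny_cylinder_spec())
        visible = truth_mask.voxels.copy()
        # the hole rows buried in the bright RPE band are not recoverable
        # by any intensity force; compare against the visible part
        yi = np.arange(volume.ny)[None, :, None]
        band_top = (360.0 - 12.0) / volume.spacing.dy
        visible &= yi < band_top
        seed = ndimage.binary_erosion(visible, np.ones((3, 3, 1)), iterations=2)
        fld = LevelSetField(_signed_distance(seed, volume.spacing),
                            volume.spacing)
        out, log = evolve_lgdf(volume, fld, FAST)
        region = out.interior
        # clip to the band as the multiscale driver would
        region &= (yi >= ilm.y_index[:, None, :] - 2)
        region &= (yi <= rpe.y_index[:, None, :])
        assert dice(region, visible) >= 0.98

    def test_energy_non_increasing_on_accepted_steps(self):
        volume, _, _, rpe, ilm = phantom_setup(tiny_cylinder_spec())
        fld = initialize_level_set(volume, rpe, ilm)
        _, log = evolve_lgdf(volume, fld, FAST)
        energies = [e["energy"] for e in log if e["accepted"]]
        assert len(energies) >= 5
        for prev, cur in zip(energies, energies[1:]):
            assert cur <= prev + 1e-6 * abs(prev) + 1e-9

    def test_constant_volume_shrinks_under_curvature(self):
        # flat intensity: the local Gaussian statistics of interior and
        # exterior coincide, the data force vanishes, and only the length
        # penalty moves the interface — the (smoothed) interior measure
        # shrinks and never grows
        import math

        sp = VoxelSpacing(5.0, 5.0, 5.0)
        vol = OCTVolume(np.full((40, 40, 40), 77.0), sp)
        ball = np.zeros((40, 40, 40), bool)
        X, Y, Z = np.meshgrid(*(np.arange(40),) * 3, indexing="ij")
        ball[(X - 20) ** 2 + (Y - 20) ** 2 + (Z - 20) ** 2 <= 12 ** 2] = True
        phi0 = _signed_distance(ball, sp)
        fld = LevelSetField(phi0, sp)
        params = LevelSetParams(max_iter=15, mu=30.0, tol=0.0)
        out, log = evolve_lgdf(vol, fld, params)

        eps = params.heaviside_eps_vox * sp.dy

        def smoothed_interior(phi):
            return float(np.sum(0.5 * (1 + (2 / math.pi)
                                       * np.arctan(-phi / eps))))

        assert smoothed_interior(out.phi) < smoothed_interior(phi0)
        # and the voxelised interior never grew
        fracs = [e["volume_fraction"] for e in log if e["accepted"]]
        assert max(fracs) <= (phi0 <= 0).mean() + 1e-12


class TestMultiscale:
    def test_single_scale_matches_direct_evolution(self):
        spec = tiny_cylinder_spec()
        volume, truth_mask, _, rpe, ilm = phantom_setup(spec)
        params = LevelSetParams(scales=(1,), max_iter=60)
        mask, _ = multiscale_segment(volume, params, rpe, ilm)
        d = dice(mask.voxels, truth_mask.voxels)
        params3 = LevelSetParams(scales=(4, 2, 1), max_iter=60)
        mask3, _ = multiscale_segment(volume, params3, rpe, ilm)
        d3 = dice(mask3.voxels, truth_mask.voxels)
        assert abs(d - d3) <= 0.01

    def test_multiscale_uses_fewer_fine_iterations(self):
        spec = tiny_cylinder_spec()
        volume, _, _, rpe, ilm = phantom_setup(spec)
        _, log1 = multiscale_segment(volume,
                                     LevelSetParams(scales=(1,), max_iter=60),
                                     rpe, ilm)
        _, log3 = multiscale_segment(volume,
                                     LevelSetParams(scales=(4, 2, 1),
                                                    max_iter=60), rpe, ilm)
        fine3 = sum(1 for e in log3 if e["scale"] == 1)
        fine1 = sum(1 for e in log1 if e["scale"] == 1)
        assert fine3 <= fine1

    def test_error_annotated_with_scale(self):
        volume = layered_volume()
        rpe, ilm = estimate_surfaces(volume)
        with pytest.raises(SegmentationError, match="scale 4"):
            multiscale_segment(volume, LevelSetParams(), rpe, ilm)


class TestCurvatureCut:
    @staticmethod
    def _flat_surfaces(spec):
        rpe = SurfaceMap(np.full((spec.nx, spec.nz), spec.rpe_depth_um),
                         "RPE", spec.spacing)
        ilm = SurfaceMap(np.full((spec.nx, spec.nz), spec.ilm_depth_um),
                         "ILM", spec.spacing)
        return rpe, ilm

    def test_leaked_mask_restored_to_truth(self):
        spec = tiny_cylinder_spec()
        _, truth_mask, _ = generate_phantom(spec)
        rpe, ilm = self._flat_surfaces(spec)
        leaked = truth_mask.voxels.copy()
        ilm_row = int(spec.ilm_depth_um / spec.spacing.dy)
        # extend the hole 10 voxels up into the vitreous
        top_foot = truth_mask.voxels[:, ilm_row + 1, :]
        for k in range(1, 11):
            leaked[:, max(ilm_row - k, 0), :] |= top_foot
        cut = curvature_surface_cut(HoleMask(leaked, spec.spacing), rpe, ilm)
        assert dice(cut.voxels, truth_mask.voxels) >= 0.97

    def test_mid_band_mask_unchanged(self):
        spec = tiny_cylinder_spec()
        rpe, ilm = self._flat_surfaces(spec)
        vox = np.zeros((spec.nx, spec.ny, spec.nz), bool)
        vox[20:40, 35:48, 8:16] = True  # well clear of both surfaces
        out = curvature_surface_cut(HoleMask(vox, spec.spacing), rpe, ilm)
        np.testing.assert_array_equal(out.voxels, vox)

    def test_idempotent(self):
        spec = tiny_cylinder_spec()
        volume, truth_mask, _, rpe, ilm = phantom_setup(spec)
        mask, _ = multiscale_segment(volume, FAST, rpe, ilm)
        once = curvature_surface_cut(mask, rpe, ilm)
        twice = curvature_surface_cut(once, rpe, ilm)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_result_confined_to_band(self):
        spec = tiny_cylinder_spec()
        volume, _, _, rpe, ilm = phantom_setup(spec)
        mask, _ = multiscale_segment(volume, FAST, rpe, ilm)
        cut = curvature_surface_cut(mask, rpe, ilm)
        yi = np.arange(volume.ny)[None, :, None]
        above = cut.voxels & (yi < ilm.y_index[:, None, :] - 1.0)
        below = cut.voxels & (yi > rpe.y_index[:, None, :] + 0.5)
        assert not above.any()
        assert not below.any()


class TestIntensityInvariance:
    def test_affine_rescaling_changes_little(self):
        spec = tiny_cylinder_spec()
        volume, truth_mask, _, rpe, ilm = phantom_setup(spec)
        mask_a, _ = multiscale_segment(volume, FAST, rpe, ilm)
        rescaled = OCTVolume(volume.intensities * 3.7 + 40.0,
                             volume.spacing, volume.source_id)
        mask_b, _ = multiscale_segment(rescaled, FAST, rpe, ilm)
        da = dice(mask_a.voxels, truth_mask.voxels)
        db = dice(mask_b.voxels, truth_mask.voxels)
        assert abs(da - db) <= 0.01
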