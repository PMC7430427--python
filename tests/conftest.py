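"""Shared fixtures: fast phantoms and session-scoped pipeline runs.

The heavy end-to-end segmentations (the 10-spec recovery suite and the
speckle runs) execute once per session and are shared between the unit
and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mh3d import (EllipseSection, PhantomSpec, VoxelSpacing, generate_phantom,
                  OCTVolume)
from mh3d.pipeline import phantom_suite, segment_and_measure
from mh3d.segmentation import dice

# small, fast geometry for unit tests (~850 x 600 um footprint, H = 240 um)
TINY = dict(nx=72, ny=80, nz=25, spacing=VoxelSpacing(12.0, 6.0, 25.0),
            ilm_depth_um=120.0, rpe_depth_um=360.0)


def tiny_cylinder_spec(r_um: float = 150.0, seed: int = 0,
                       **overrides) -> PhantomSpec:
    sec = EllipseSection(r_um, r_um, 0.0)
    kw = dict(TINY, base=sec, waist=sec, top=sec, waist_fraction=0.5,
              seed=seed)
    kw.update(overrides)
    return PhantomSpec(**kw)


def tiny_hourglass_spec(seed: int = 0, **overrides) -> PhantomSpec:
    kw = dict(TINY,
              base=EllipseSection(200.0, 170.0, 0.0),
              waist=EllipseSection(110.0, 90.0, 0.0),
              top=EllipseSection(150.0, 130.0, 0.0),
              waist_fraction=0.5, seed=seed)
    kw.update(overrides)
    return PhantomSpec(**kw)


def layered_volume(nx=60, ny=90, nz=20, dx=8.0, dy=5.0, dz=25.0,
                   ilm_um=50.0, rpe_um=350.0, band_um=20.0,
                   tilt_x: float = 0.0,
                   levels=(25.0, 160.0, 240.0, 90.0)) -> OCTVolume:
    """Hole-free three-band volume; optional RPE tilt (um of depth per um
    of X) about the Z axis."""
    vit, ret, rpe_level, sub = levels
    x_um = np.arange(nx) * dx
    y_um = np.arange(ny) * dy
    cx = x_um.mean()
    rpe_y = rpe_um + (x_um - cx) * tilt_x  # (nx,)
    data = np.full((nx, ny, nz), vit, dtype=np.float32)
    Y = y_um[None, :]
    R = rpe_y[:, None]
    prof = np.where(Y < ilm_um, vit,
                    np.where(Y < R - band_um / 2, ret,
                             np.where(Y <= R + band_um / 2, rpe_level, sub)))
    data[:] = prof[:, :, None]
    return OCTVolume(data, VoxelSpacing(dx, dy, dz), "layered")


@pytest.fixture(scope="session")
def tiny_cylinder():
    spec = tiny_cylinder_spec()
    volume, truth_mask, truth = generate_phantom(spec)
    return spec, volume, truth_mask, truth


@pytest.fixture(scope="session")
def tiny_hourglass():
    spec = tiny_hourglass_spec()
    volume, truth_mask, truth = generate_phantom(spec)
    return spec, volume, truth_mask, truth


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_cylinder):
    spec, volume, truth_mask, truth = tiny_cylinder
    result = segment_and_measure(volume)
    return spec, volume, truth_mask, truth, result


@pytest.fixture(scope="session")
def recovery_suite():
    """The 10-spec noiseless recovery suite, run end to end once."""
    out = []
    for spec in phantom_suite(10, seed=7):
        volume, truth_mask, truth = generate_phantom(spec)
        result = segment_and_measure(volume)
        d = dice(result.mask_original.voxels, truth_mask.voxels)
        out.append({"spec": spec, "truth": truth, "truth_mask": truth_mask,
                    "result": result, "dice": d})
    return out


@pytest.fixture(scope="session")
def speckle_suite():
    """Three speckle (s = 0.2) phantoms, run end to end once."""
    out = []
    for spec in phantom_suite(3, seed=11, speckle=0.2):
        volume, truth_mask, truth = generate_phantom(spec)
        result = segment_and_measure(volume)
        d = dice(result.mask_original.voxels, truth_mask.voxels)
        out.append({"spec": spec, "truth": truth, "truth_mask": truth_mask,
                    "result": result, "dice": d})
    return out


def angle_diff_deg(a: float, b: float) -> float:
    """Axial (mod 180) angular distance."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
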