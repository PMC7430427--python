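"""Synthetic OCT phantoms with a parametric full-thickness macular hole.

The phantom emulates the clinical macular-cube geometry: a dark vitreous,
a mid-reflective retinal slab between the ILM and the RPE, a thin bright
RPE band, and a full-thickness hole punched through the neural retina.
The hole is the solid swept between three elliptical cross-sections —
base (at the RPE plane), waist, and top (at the ILM) — with piecewise
linear interpolation of semi-axes, meridian and centre along height, so
the family covers cylinders, cones, hourglasses, rotated ellipses and
vertically tilted holes.  Every shape parameter the morphometry measures
has an exact analytic value (closed form, or quadrature at a recorded
step), which makes the phantom the ground-truth oracle for the whole
pipeline.

Speckle is modelled as multiplicative Gamma noise with mean 1, the
standard surrogate for OCT speckle statistics.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .oct_io import HoleMask, OCTVolume, VoxelSpacing

__all__ = [
    "EllipseSection",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "add_speckle_noise",
    "analytic_truth",
    "hole_profile_at",
    "rasterize_hole",
]


@dataclass(frozen=True)
class EllipseSection:
    """One elliptical cross-section: semi-axes (um) and meridian (deg).

    ``theta_deg`` is the orientation of the ``a`` axis in the en-face XZ
    plane, measured from +X, interpreted mod 180.
    """

    a_um: float
    b_um: float
    theta_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.a_um <= 0 or self.b_um <= 0:
            raise ValueError(f"ellipse semi-axes must be > 0, got "
                             f"({self.a_um}, {self.b_um})")

    @property
    def area_um2(self) -> float:
        return math.pi * self.a_um * self.b_um


def _wrap180(angle: float) -> float:
    return angle % 180.0


def _interp_angle(theta1: float, theta2: float, t: float) -> float:
    """Linear interpolation of axial angles along the shorter arc (mod 180)."""
    d = (theta2 - theta1 + 90.0) % 180.0 - 90.0
    return _wrap180(theta1 + t * d)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic macular-hole volume.

    Geometry: grid dims, voxel spacing, ILM/RPE depths (um from the top of
    the frame; depth increases downward so ``rpe_depth_um >
    ilm_depth_um``).  Hole: base/waist/top ellipses, the waist's height
    fraction ``waist_fraction`` in (0, 1), and the lateral offset of the
    top centre relative to the base centre (``tilt_x_um, tilt_z_um``).
    Intensities are arbitrary reflectivity units; ``speckle`` is the
    multiplicative noise SD (0 = noiseless).
    """

    nx: int
    ny: int
    nz: int
    spacing: VoxelSpacing
    ilm_depth_um: float
    rpe_depth_um: float
    base: EllipseSection
    waist: EllipseSection
    top: EllipseSection
    waist_fraction: float = 0.5
    tilt_x_um: float = 0.0
    tilt_z_um: float = 0.0
    centre_x_um: float | None = None
    centre_z_um: float | None = None
    vitreous_level: float = 25.0
    retina_level: float = 160.0
    rpe_level: float = 240.0
    sub_rpe_level: float = 90.0
    rpe_band_um: float = 24.0
    speckle: float = 0.0
    seed: int = 0
    operculum: bool = False
    strict_hourglass: bool = False

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 2:
            raise ValueError("grid must be >= 2 voxels per axis")
        if not 0.0 < self.waist_fraction < 1.0:
            raise ValueError("waist_fraction must lie in (0, 1)")
        if self.rpe_depth_um <= self.ilm_depth_um:
            raise ValueError("RPE depth must exceed ILM depth")
        if self.speckle < 0:
            raise ValueError("speckle scale must be >= 0")
        if self.strict_hourglass and (
                self.waist.area_um2 > self.base.area_um2
                and self.waist.area_um2 > self.top.area_um2):
            raise ValueError("strict hourglass requested but the waist is "
                             "larger than both base and top")
        self._check_footprint()

    # -- geometry helpers --------------------------------------------------

    @property
    def hole_height_um(self) -> float:
        return self.rpe_depth_um - self.ilm_depth_um

    @property
    def base_centre_um(self) -> tuple[float, float]:
        cx = self.centre_x_um
        cz = self.centre_z_um
        if cx is None:
            cx = 0.5 * (self.nx - 1) * self.spacing.dx
        if cz is None:
            cz = 0.5 * (self.nz - 1) * self.spacing.dz
        return float(cx), float(cz)

    def _check_footprint(self) -> None:
        fx = (self.nx - 1) * self.spacing.dx
        fz = (self.nz - 1) * self.spacing.dz
        cx0, cz0 = self.base_centre_um
        for frac, sec in ((0.0, self.base), (self.waist_fraction, self.waist),
                          (1.0, self.top)):
            th = math.radians(sec.theta_deg)
            # bounding half-extents of a rotated ellipse
            ex = math.hypot(sec.a_um * math.cos(th), sec.b_um * math.sin(th))
            ez = math.hypot(sec.a_um * math.sin(th), sec.b_um * math.cos(th))
            cx = cx0 + frac * self.tilt_x_um
            cz = cz0 + frac * self.tilt_z_um
            if cx - ex < 0 or cx + ex > fx or cz - ez < 0 or cz + ez > fz:
                raise ValueError(
                    f"hole section at height fraction {frac:.2f} exceeds the "
                    f"volume footprint ({fx:.0f} x {fz:.0f} um)")
        if self.rpe_depth_um + self.rpe_band_um / 2 > (self.ny - 1) * self.spacing.dy:
            raise ValueError("RPE band does not fit inside the depth range")
        if self.ilm_depth_um < self.spacing.dy:
            raise ValueError("ILM too close to the top of the frame")


def hole_profile_at(spec: PhantomSpec, h_um: float
                    ) -> tuple[float, float, float, float, float]:
    """Hole cross-section at height ``h_um`` above the RPE plane.

    Returns ``(a, b, theta_deg, cx, cz)`` in um/deg.  Semi-axes and
    meridian interpolate piecewise linearly base->waist->top; the centre
    drifts linearly from the base centre to the tilted top centre.
    """
    H = spec.hole_height_um
    t = min(max(h_um / H, 0.0), 1.0)
    fw = spec.waist_fraction
    if t <= fw:
        s = t / fw
        a = spec.base.a_um + s * (spec.waist.a_um - spec.base.a_um)
        b = spec.base.b_um + s * (spec.waist.b_um - spec.base.b_um)
        th = _interp_angle(spec.base.theta_deg, spec.waist.theta_deg, s)
    else:
        s = (t - fw) / (1.0 - fw)
        a = spec.waist.a_um + s * (spec.top.a_um - spec.waist.a_um)
        b = spec.waist.b_um + s * (spec.top.b_um - spec.waist.b_um)
        th = _interp_angle(spec.waist.theta_deg, spec.top.theta_deg, s)
    cx0, cz0 = spec.base_centre_um
    return a, b, th, cx0 + t * spec.tilt_x_um, cz0 + t * spec.tilt_z_um


@dataclass
class PhantomTruth:
    """Exact morphometry of a :class:`PhantomSpec` (um / um^2 / um^3 / deg).

    Closed forms where available (ellipse area pi*a*b, ellipse Feret
    diameters 2a and 2b, misalignment sqrt(dx^2+dz^2)); volume, minimum
    area and lateral surface by quadrature at ``quadrature_step_um``.
    """

    ba_min_um: float
    ba_max_um: float
    ba_angle_min_deg: float
    ba_angle_max_deg: float
    ma_min_um: float
    ma_max_um: float
    ma_angle_min_deg: float
    ma_angle_max_deg: float
    ma_height_um: float
    ma_area_um2: float
    base_area_um2: float
    top_area_um2: float
    hole_height_um: float
    volume_um3: float
    surface_area_um2: float
    centre_misalignment_um: float
    quadrature_step_um: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _feret_of_ellipse(a: float, b: float, theta: float
                      ) -> tuple[float, float, float, float]:
    """(min, max, angle_min, angle_max) Feret of an ellipse; angles mod 180."""
    if a >= b:
        return 2 * b, 2 * a, _wrap180(theta + 90.0), _wrap180(theta)
    return 2 * a, 2 * b, _wrap180(theta), _wrap180(theta + 90.0)


def analytic_truth(spec: PhantomSpec, step_um: float = 0.5,
                   n_theta: int = 720) -> PhantomTruth:
    """Exact parameter set for a phantom, independent of any raster.

    Volume integrates the section area (a piecewise-quadratic function of
    height) with Simpson's rule per linear segment, which is exact.  The
    minimum-area section is located by dense sampling of the central
    20%-90% height band at ``step_um``; the lateral surface is a fine
    triangulated sweep at the same height step with ``n_theta`` angular
    samples, closed by the base and top caps.
    """
    if step_um <= 0 or step_um > 1.0:
        raise ValueError("quadrature step must lie in (0, 1] um")
    H = spec.hole_height_um
    fw = spec.waist_fraction

    def area(h: float) -> float:
        a, b, _, _, _ = hole_profile_at(spec, h)
        return math.pi * a * b

    # exact volume: Simpson per linear-in-h segment (integrand quadratic)
    vol = 0.0
    for h0, h1 in ((0.0, fw * H), (fw * H, H)):
        vol += (h1 - h0) / 6.0 * (area(h0) + 4 * area(0.5 * (h0 + h1)) + area(h1))

    # minimum-area section in the central 20-90% band; ties -> lowest height
    hs = np.arange(0.2 * H, 0.9 * H + 0.5 * step_um, step_um)
    hs = np.clip(hs, 0.2 * H, 0.9 * H)
    if fw * H not in hs and 0.2 * H <= fw * H <= 0.9 * H:
        hs = np.sort(np.append(hs, fw * H))
    areas = np.array([area(h) for h in hs])
    i = int(np.argmin(np.round(areas, 9)))  # stable tie-break at equal areas
    ma_h = float(hs[i])
    ma_a, ma_b, ma_th, _, _ = hole_profile_at(spec, ma_h)
    ma_min, ma_max, ma_angle_min, ma_angle_max = _feret_of_ellipse(ma_a, ma_b, ma_th)

    ba_min, ba_max, ba_angle_min, ba_angle_max = _feret_of_ellipse(
        spec.base.a_um, spec.base.b_um, spec.base.theta_deg)

    # lateral surface: triangulated sweep of the elliptical boundary
    hgrid = np.arange(0.0, H + 0.5 * step_um, step_um)
    hgrid[-1] = min(hgrid[-1], H)
    prof = np.array([hole_profile_at(spec, h) for h in hgrid])
    th_p = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
    ct, st = np.cos(th_p), np.sin(th_p)
    # unwrap the meridian sequence (period 180 deg) so consecutive loops
    # share a continuous parametrisation — a wrapped jump would twist the
    # swept mesh half a turn between loops
    th_seq = prof[:, 2]
    d = (np.diff(th_seq) + 90.0) % 180.0 - 90.0
    th_cont = np.concatenate([[th_seq[0]], th_seq[0] + np.cumsum(d)])
    ang = np.radians(th_cont)[:, None]
    px = (prof[:, 0][:, None] * ct * np.cos(ang)
          - prof[:, 1][:, None] * st * np.sin(ang)) + prof[:, 3][:, None]
    pz = (prof[:, 0][:, None] * ct * np.sin(ang)
          + prof[:, 1][:, None] * st * np.cos(ang)) + prof[:, 4][:, None]
    py = np.broadcast_to(hgrid[:, None], px.shape)
    lateral = _mesh_area_closed_loops(px, py, pz)

    base_area = spec.base.area_um2
    top_area = spec.top.area_um2
    surface = lateral + base_area + top_area

    mis = math.hypot(spec.tilt_x_um, spec.tilt_z_um)
    return PhantomTruth(
        ba_min_um=ba_min, ba_max_um=ba_max,
        ba_angle_min_deg=ba_angle_min, ba_angle_max_deg=ba_angle_max,
        ma_min_um=ma_min, ma_max_um=ma_max,
        ma_angle_min_deg=ma_angle_min, ma_angle_max_deg=ma_angle_max,
        ma_height_um=ma_h, ma_area_um2=float(areas[i]),
        base_area_um2=base_area, top_area_um2=top_area,
        hole_height_um=H, volume_um3=vol, surface_area_um2=surface,
        centre_misalignment_um=mis, quadrature_step_um=step_um)


def _mesh_area_closed_loops(px: np.ndarray, py: np.ndarray,
                            pz: np.ndarray) -> float:
    """Total area of the quad strip between consecutive closed loops."""
    # wrap the angular axis
    pxw = np.concatenate([px, px[:, :1]], axis=1)
    pyw = np.concatenate([py, py[:, :1]], axis=1)
    pzw = np.concatenate([pz, pz[:, :1]], axis=1)
    p = np.stack([pxw, pyw, pzw], axis=-1)  # (nh, nt+1, 3)
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, :-1]
    d = p[1:, 1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(d - b, d - c), axis=-1)
    return float(t1.sum() + t2.sum())


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------


def rasterize_hole(spec: PhantomSpec) -> np.ndarray:
    """Boolean (nx, ny, nz) raster of the analytic hole solid.

    A voxel (centre at index x spacing) is inside if its height above the
    RPE plane lies in [0, H] and its (x, z) position falls inside the
    interpolated ellipse at that height.
    """
    sp = spec.spacing
    x_um = np.arange(spec.nx) * sp.dx
    z_um = np.arange(spec.nz) * sp.dz
    X, Z = np.meshgrid(x_um, z_um, indexing="ij")
    mask = np.zeros((spec.nx, spec.ny, spec.nz), dtype=bool)
    H = spec.hole_height_um
    for iy in range(spec.ny):
        h = spec.rpe_depth_um - iy * sp.dy
        if h < 0 or h > H:
            continue
        a, b, th, cx, cz = hole_profile_at(spec, h)
        thr = math.radians(th)
        u = X - cx
        w = Z - cz
        ur = u * math.cos(thr) + w * math.sin(thr)
        wr = -u * math.sin(thr) + w * math.cos(thr)
        mask[:, iy, :] = (ur / a) ** 2 + (wr / b) ** 2 <= 1.0
    return mask


def _layered_intensities(spec: PhantomSpec) -> np.ndarray:
    """Vitreous / retina / RPE-band / sub-RPE depth profile, broadcast 3D."""
    sp = spec.spacing
    y_um = np.arange(spec.ny) * sp.dy
    half = spec.rpe_band_um / 2.0
    prof = np.full(spec.ny, spec.vitreous_level, dtype=np.float32)
    prof[(y_um >= spec.ilm_depth_um)] = spec.retina_level
    prof[np.abs(y_um - spec.rpe_depth_um) <= half] = spec.rpe_level
    prof[y_um > spec.rpe_depth_um + half] = spec.sub_rpe_level
    return np.broadcast_to(prof[None, :, None],
                           (spec.nx, spec.ny, spec.nz)).copy()


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[OCTVolume, HoleMask, PhantomTruth]:
    """Render a phantom volume, its ground-truth hole mask and exact truth.

    The intensity volume carries the layered background with the hole
    region set to vitreous reflectivity; the bright RPE band is left
    intact beneath the hole (a full-thickness hole stops at the RPE).
    The truth mask is the rasterised analytic solid, which extends down
    to the RPE plane itself; truth parameters come from
    :func:`analytic_truth`, never from the raster.
    """
    vol = _layered_intensities(spec)
    hole = rasterize_hole(spec)

    sp = spec.spacing
    y_um = np.arange(spec.ny) * sp.dy
    above_band = y_um < spec.rpe_depth_um - spec.rpe_band_um / 2.0
    carve = hole & above_band[None, :, None]
    vol[carve] = spec.vitreous_level

    if spec.operculum:
        _render_operculum(spec, vol)

    volume = OCTVolume(vol, sp, source_id=f"phantom-seed{spec.seed}")
    if spec.speckle > 0:
        volume = add_speckle_noise(volume, spec.speckle, spec.seed)
    truth = analytic_truth(spec)
    return volume, HoleMask(hole, sp), truth


def _render_operculum(spec: PhantomSpec, vol: np.ndarray) -> None:
    """Draw a floating tissue flap above the hole (not part of the hole)."""
    sp = spec.spacing
    cx, cz = spec.base_centre_um
    cx += spec.tilt_x_um
    cz += spec.tilt_z_um
    cy = max(spec.ilm_depth_um - 60.0, 3 * sp.dy)
    rx, ry, rz = 0.45 * spec.top.a_um, 18.0, 0.45 * spec.top.b_um
    x_um = np.arange(spec.nx) * sp.dx
    y_um = np.arange(spec.ny) * sp.dy
    z_um = np.arange(spec.nz) * sp.dz
    X, Y, Z = np.meshgrid(x_um, y_um, z_um, indexing="ij")
    blob = (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2
            + ((Z - cz) / rz) ** 2) <= 1.0
    vol[blob] = spec.retina_level


def add_speckle_noise(volume: OCTVolume, s: float, seed: int) -> OCTVolume:
    """Multiplicative Gamma speckle: each voxel scaled by an i.i.d. factor
    with mean 1 and standard deviation ``s`` (Gamma(k=1/s^2, theta=s^2)).

    ``s = 0`` returns the input unchanged; a fixed seed reproduces the
    output bit-exactly.
    """
    if s < 0:
        raise ValueError("speckle scale must be >= 0")
    if s == 0:
        return volume
    rng = np.random.default_rng(seed)
    k = 1.0 / (s * s)
    factors = rng.gamma(shape=k, scale=s * s,
                        size=volume.intensities.shape).astype(np.float32)
    noisy = volume.intensities.astype(np.float32) * factors
    return OCTVolume(noisy, volume.spacing, volume.source_id)
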