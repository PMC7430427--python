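"""Reading, writing and geometric normalisation of OCT volumes.

An SD-OCT macular cube is exported as a folder of grayscale TIFF B-scans
(one cross-sectional image per file, lexicographic filename order giving
the slow-scan Z order).  In-memory the volume is indexed ``(x, y, z)``:

* X — lateral position within a B-scan (image width),
* Y — depth, increasing from the vitreous toward the choroid,
* Z — B-scan index across the cube.

Physical coordinates are ``voxel index x spacing`` with the origin at the
top-left corner of the first B-scan.  Voxel spacing is strongly
anisotropic in clinical protocols (about 5.5 x 3.9 x 30 um), so every
downstream operator works in micrometres, never raw voxels.

The module also estimates the two reference surfaces the morphometry is
anchored to — the bright retinal pigment epithelium (RPE) band and the
internal limiting membrane (ILM) — and can flatten a volume so the RPE
becomes a constant-depth plane, which turns "RPE-parallel section" into
"grid slice".
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "VoxelSpacing",
    "OCTVolume",
    "SurfaceMap",
    "HoleMask",
    "SurfaceParams",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_spacing_metadata",
    "write_spacing_metadata",
    "estimate_surfaces",
    "flatten_volume",
    "unflatten_volume",
    "write_surface_csv",
    "read_surface_csv",
]

#: Z line spacing assumed when a volume arrives without metadata (um).
DEFAULT_DZ_UM = 30.0


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel pitch in micrometres.

    dx : um per pixel along X (within B-scan, horizontal)
    dy : um per pixel along Y (depth)
    dz : um per B-scan step along Z
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"spacing {name} must be finite and > 0, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.dx * self.dy * self.dz

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


@dataclass
class OCTVolume:
    """A 3D OCT intensity grid with physical spacing.

    ``intensities`` has shape ``(nx, ny, nz)`` and non-negative values.
    """

    intensities: np.ndarray
    spacing: VoxelSpacing
    source_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {a.shape}")
        if any(s < 2 for s in a.shape):
            raise ValueError(f"every axis must have >= 2 voxels, got shape {a.shape}")
        if a.size and float(a.min()) < 0:
            raise ValueError("intensities must be non-negative")
        self.intensities = a

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def nx(self) -> int:
        return self.intensities.shape[0]

    @property
    def ny(self) -> int:
        return self.intensities.shape[1]

    @property
    def nz(self) -> int:
        return self.intensities.shape[2]

    def copy(self) -> "OCTVolume":
        return OCTVolume(self.intensities.copy(), self.spacing, self.source_id)


@dataclass
class SurfaceMap:
    """Height map giving the Y depth (um) of a retinal surface per (x, z).

    ``y_um`` has shape ``(nx, nz)``; ``kind`` is ``"RPE"`` or ``"ILM"``.
    Depth increases downward, so the ILM (inner surface) has smaller
    ``y_um`` than the RPE everywhere.
    """

    y_um: np.ndarray
    kind: str
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.y_um.ndim != 2:
            raise ValueError("surface map must be 2D over (x, z)")
        if self.kind not in ("RPE", "ILM"):
            raise ValueError(f"kind must be 'RPE' or 'ILM', got {self.kind!r}")
        if not np.all(np.isfinite(self.y_um)):
            raise ValueError("surface map contains non-finite values")

    @property
    def y_index(self) -> np.ndarray:
        """Surface position in (fractional) voxel indices along Y."""
        return self.y_um / self.spacing.dy


@dataclass
class HoleMask:
    """Binary 3D mask of a segmented macular hole, aligned to its volume."""

    voxels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxels = v.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def copy(self) -> "HoleMask":
        return HoleMask(self.voxels.copy(), self.spacing)


# ---------------------------------------------------------------------------
# TIFF stack IO
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = (".tif", ".tiff")


def _list_tiffs(folder: Path) -> list[Path]:
    files = sorted(
        p for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in _TIFF_SUFFIXES
    )
    return files


def read_tiff_stack(folder: str | os.PathLike, spacing: VoxelSpacing,
                    source_id: str | None = None) -> OCTVolume:
    """Read a folder of grayscale TIFF B-scans into an :class:`OCTVolume`.

    Lexicographic filename order defines the Z order.  Every image must be
    single-channel and share the same (width, height); intensities are
    preserved bit-exactly.

    Raises
    ------
    FileNotFoundError
        If the folder does not exist.
    ValueError
        Empty folder, fewer than two slices, mismatched dimensions or a
        non-grayscale image — the message names the offending file.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"not a directory: {folder}")
    files = _list_tiffs(folder)
    if not files:
        raise ValueError(f"no TIFF files found in {folder}")
    if len(files) < 2:
        raise ValueError(f"need >= 2 B-scans, found {len(files)} in {folder}")

    slices = []
    shape0 = None
    for f in files:
        img = tifffile.imread(f)
        if img.ndim != 2:
            raise ValueError(f"not a single-channel grayscale image: {f.name} "
                             f"(shape {img.shape})")
        if shape0 is None:
            shape0 = img.shape
        elif img.shape != shape0:
            raise ValueError(
                f"B-scan dimension mismatch: {f.name} has shape {img.shape}, "
                f"expected {shape0} (from {files[0].name})")
        slices.append(img)

    # image raster is (row=Y, col=X); volume is (X, Y, Z)
    data = np.stack(slices, axis=-1).transpose(1, 0, 2)
    return OCTVolume(data, spacing, source_id or folder.name)


def write_tiff_stack(volume_or_mask: OCTVolume | HoleMask,
                     folder: str | os.PathLike, prefix: str = "scan") -> list[Path]:
    """Write a volume (or mask, as 0/255 uint8) as one TIFF per B-scan.

    Filenames are ``{prefix}_{z:04d}.tiff`` so lexicographic order restores
    Z order.  Uncompressed output; round trips bit-exactly through
    :func:`read_tiff_stack`.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    if isinstance(volume_or_mask, HoleMask):
        data = volume_or_mask.voxels.astype(np.uint8) * 255
    else:
        data = volume_or_mask.intensities
    paths = []
    for z in range(data.shape[2]):
        # back to image raster (Y, X)
        img = np.ascontiguousarray(data[:, :, z].T)
        p = folder / f"{prefix}_{z:04d}.tiff"
        tifffile.imwrite(p, img, compression=None)
        paths.append(p)
    return paths


def read_spacing_metadata(path: str | os.PathLike) -> tuple[VoxelSpacing, str]:
    """Read a ``key=value`` sidecar file (dx_um, dy_um, dz_um, source_id).

    A missing dz_um falls back to 30 um (typical line spacing) with a
    warning via the return value's source text; dx_um and dy_um are
    required.
    """
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad metadata line (expected key=value): {line!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    try:
        dx = float(kv["dx_um"])
        dy = float(kv["dy_um"])
    except KeyError as e:
        raise ValueError(f"metadata missing required key {e}") from e
    dz = float(kv.get("dz_um", DEFAULT_DZ_UM))
    if "dz_um" not in kv:
        import warnings

        warnings.warn(f"dz_um absent from {path}; assuming {DEFAULT_DZ_UM} um",
                      stacklevel=2)
    return VoxelSpacing(dx, dy, dz), kv.get("source_id", "")


def write_spacing_metadata(path: str | os.PathLike, spacing: VoxelSpacing,
                           source_id: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"dx_um={spacing.dx}\ndy_um={spacing.dy}\ndz_um={spacing.dz}\n")
        if source_id:
            fh.write(f"source_id={source_id}\n")


def write_surface_csv(surface: SurfaceMap, path: str | os.PathLike) -> None:
    """Write a surface as CSV rows (x_index, z_index, y_um)."""
    nx, nz = surface.y_um.shape
    xi, zi = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
    import pandas as pd

    pd.DataFrame({
        "x_index": xi.ravel(),
        "z_index": zi.ravel(),
        "y_um": surface.y_um.ravel(),
    }).to_csv(path, index=False)


def read_surface_csv(path: str | os.PathLike, kind: str,
                     spacing: VoxelSpacing) -> SurfaceMap:
    import pandas as pd

    df = pd.read_csv(path)
    nx = int(df["x_index"].max()) + 1
    nz = int(df["z_index"].max()) + 1
    y = np.full((nx, nz), np.nan)
    y[df["x_index"].to_numpy(), df["z_index"].to_numpy()] = df["y_um"].to_numpy()
    return SurfaceMap(y, kind, spacing)


# ---------------------------------------------------------------------------
# Reference-surface estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceParams:
    """Detector settings for :func:`estimate_surfaces`.

    smooth_sigma_y : Gaussian smoothing along depth before detection (voxels).
    ilm_fraction : ILM = first depth where the smoothed A-scan exceeds this
        fraction of its RPE peak.
    median_size : lateral median-filter window applied to each raw map (px).
    lateral_sigma : lateral Gaussian smoothing of each map (px).
    max_bad_fraction : tolerated fraction of undetectable A-scan columns
        before the whole estimation is declared failed.
    min_thickness_um : columns whose ILM–RPE separation falls below this are
        treated as hole/opening columns; their ILM is inpainted from the
        surrounding retina.
    ilm_bridge_um : localized ILM depressions narrower than this (the open
        top of a hole, or the dip where a hole wall overhangs) are bridged
        by a grey-scale morphological opening of the depth map, so the ILM
        reference spans the hole like the surrounding inner surface.
        0 disables bridging.
    """

    smooth_sigma_y: float = 1.0
    ilm_fraction: float = 0.5
    median_size: int = 5
    lateral_sigma: float = 2.0
    max_bad_fraction: float = 0.05
    min_thickness_um: float = 60.0
    ilm_bridge_um: float = 900.0


class SurfaceEstimationError(RuntimeError):
    pass


def _subvoxel_peak(profile: np.ndarray, idx: int) -> float:
    """Parabolic refinement of an argmax index."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(idx)
    delta = 0.5 * (y0 - y2) / denom
    return float(idx) + float(np.clip(delta, -0.5, 0.5))


def _first_crossing(profile: np.ndarray, level: float) -> float | None:
    """First (fractional) index where profile rises through `level`."""
    above = profile >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    y0, y1 = profile[i - 1], profile[i]
    if y1 == y0:
        return float(i)
    return (i - 1) + float((level - y0) / (y1 - y0))


def _inpaint_nan(field: np.ndarray) -> np.ndarray:
    """Fill NaNs by iterative neighbour diffusion (Laplace-style)."""
    out = field.copy()
    bad = ~np.isfinite(out)
    if not bad.any():
        return out
    if bad.all():
        raise SurfaceEstimationError("surface undetectable everywhere")
    # seed with nearest valid value, then relax
    idx = ndimage.distance_transform_edt(bad, return_distances=False,
                                         return_indices=True)
    out = out[tuple(idx)]
    k = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])
    for _ in range(50):
        sm = ndimage.convolve(out, k, mode="nearest")
        out[bad] = sm[bad]
    return out


def estimate_surfaces(volume: OCTVolume,
                      params: SurfaceParams | None = None
                      ) -> tuple[SurfaceMap, SurfaceMap]:
    """Estimate the RPE and ILM surfaces of a volume.

    Per A-scan column: the RPE is the depth of the dominant bright band
    (argmax after Gaussian smoothing along Y, parabolic sub-voxel
    refinement); the ILM is the first depth where the smoothed intensity
    exceeds ``ilm_fraction`` of that column's RPE peak (linear sub-sample
    refinement).  Columns where the two surfaces nearly coincide — the
    open top of a full-thickness hole — are inpainted from neighbouring
    retina.  Both maps are median-filtered and Gaussian-smoothed laterally.

    Returns ``(rpe, ilm)`` with ``ilm.y_um < rpe.y_um`` everywhere.

    Raises
    ------
    SurfaceEstimationError
        Constant-intensity volume, or more than ``max_bad_fraction`` of
        columns with no detectable band (the failing columns are listed).
    """
    p = params or SurfaceParams()
    data = volume.intensities.astype(float)
    nx, ny, nz = data.shape
    if float(data.max()) == float(data.min()):
        raise SurfaceEstimationError("constant-intensity volume: no band detectable")

    sm = ndimage.gaussian_filter1d(data, p.smooth_sigma_y, axis=1, mode="nearest")

    rpe_idx = np.full((nx, nz), np.nan)
    ilm_idx = np.full((nx, nz), np.nan)
    bad_cols: list[tuple[int, int]] = []
    # per-column dynamic range guard: a column is "detectable" if its band
    # contrast exceeds 5% of the global range
    global_rng = float(data.max() - data.min())
    for z in range(nz):
        col_block = sm[:, :, z]
        peaks = np.argmax(col_block, axis=1)
        for x in range(nx):
            prof = col_block[x]
            pk = int(peaks[x])
            if prof[pk] - prof.min() < 0.05 * global_rng:
                bad_cols.append((x, z))
                continue
            rpe_idx[x, z] = _subvoxel_peak(prof, pk)
            level = p.ilm_fraction * prof[pk]
            cr = _first_crossing(prof[: pk + 1], level)
            ilm_idx[x, z] = cr if cr is not None else float(pk)

    if len(bad_cols) > p.max_bad_fraction * nx * nz:
        raise SurfaceEstimationError(
            f"{len(bad_cols)} of {nx * nz} columns have no detectable band; "
            f"first few: {bad_cols[:10]}")
    if bad_cols:
        b = np.zeros((nx, nz), bool)
        for x, z in bad_cols:
            b[x, z] = True
        rpe_idx[b] = np.nan
        ilm_idx[b] = np.nan
    rpe_idx = _inpaint_nan(rpe_idx)
    ilm_idx = _inpaint_nan(ilm_idx)

    dy = volume.spacing.dy
    # hole columns: ILM collapses onto the RPE band; inpaint those laterally
    thin = (rpe_idx - ilm_idx) * dy < p.min_thickness_um
    if thin.any() and not thin.all():
        ilm_idx = ilm_idx.copy()
        ilm_idx[thin] = np.nan
        ilm_idx = _inpaint_nan(ilm_idx)
    if p.ilm_bridge_um > 0:
        # bridge depressions (deeper = larger index) narrower than the
        # widest plausible hole opening
        wx = min(nx, 2 * int(np.ceil(0.5 * p.ilm_bridge_um / volume.spacing.dx)) + 1)
        wz = min(nz, 2 * int(np.ceil(0.5 * p.ilm_bridge_um / volume.spacing.dz)) + 1)
        ilm_idx = ndimage.grey_opening(ilm_idx, size=(wx, wz), mode="nearest")

    if p.median_size > 1:
        rpe_idx = ndimage.median_filter(rpe_idx, size=p.median_size, mode="nearest")
        ilm_idx = ndimage.median_filter(ilm_idx, size=p.median_size, mode="nearest")
    if p.lateral_sigma > 0:
        rpe_idx = ndimage.gaussian_filter(rpe_idx, p.lateral_sigma, mode="nearest")
        ilm_idx = ndimage.gaussian_filter(ilm_idx, p.lateral_sigma, mode="nearest")

    # enforce the depth ordering ILM above (smaller y than) RPE
    ilm_idx = np.minimum(ilm_idx, rpe_idx - 1.0)
    ilm_idx = np.clip(ilm_idx, 0, ny - 1)

    sp = volume.spacing
    return (SurfaceMap(rpe_idx * dy, "RPE", sp), SurfaceMap(ilm_idx * dy, "ILM", sp))


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


@dataclass
class FlattenInfo:
    """Bookkeeping to invert :func:`flatten_volume` exactly.

    shifts : integer per-column shift applied along Y (positive = moved
        deeper).
    pad_top, pad_bottom : voxels of padding added along Y.
    rpe_level_index : the common Y index of the RPE in the flattened frame.
    background : fill value used for padding.
    original_ny : Y extent of the input volume.
    """

    shifts: np.ndarray
    pad_top: int
    pad_bottom: int
    rpe_level_index: int
    background: float
    original_ny: int


def flatten_volume(volume: OCTVolume, rpe: SurfaceMap,
                   ilm: SurfaceMap | None = None,
                   background: float = 0.0
                   ) -> tuple[OCTVolume, SurfaceMap | None, FlattenInfo]:
    """Shift each A-scan column by whole voxels so the RPE is a constant plane.

    No interpolation: intensities are moved by integer offsets, so the
    voxel population (histogram) is preserved exactly and the operation is
    invertible via :func:`unflatten_volume`.  If a shift would push tissue
    outside the grid the volume is padded along Y with ``background`` —
    tissue is never cropped.

    Returns the flattened volume, the ILM surface re-expressed in the
    flattened frame (if given), and a :class:`FlattenInfo`.
    """
    data = volume.intensities
    nx, ny, nz = data.shape
    rpe_i = np.rint(rpe.y_index).astype(int)
    target = int(np.rint(np.median(rpe_i)))
    shifts = target - rpe_i  # positive: column moves deeper (toward larger y)

    pad_top = max(0, int(-shifts.min()))
    pad_bottom = max(0, int(shifts.max()))
    ny_out = ny + pad_top + pad_bottom
    out = np.full((nx, ny_out, nz), background, dtype=data.dtype)

    # place each column at offset pad_top + shift
    for s in np.unique(shifts):
        sel = shifts == s
        off = pad_top + int(s)
        cols = np.where(sel)
        out[cols[0], off:off + ny, cols[1]] = data[cols[0], :, cols[1]]

    info = FlattenInfo(shifts=shifts, pad_top=pad_top, pad_bottom=pad_bottom,
                       rpe_level_index=target + pad_top, background=background,
                       original_ny=ny)
    flat = OCTVolume(out, volume.spacing, volume.source_id)

    flat_ilm = None
    if ilm is not None:
        dy = volume.spacing.dy
        flat_ilm = SurfaceMap((ilm.y_index + shifts + pad_top) * dy, "ILM",
                              volume.spacing)
    return flat, flat_ilm, info


def unflatten_volume(flat: OCTVolume, info: FlattenInfo) -> OCTVolume:
    """Exact inverse of :func:`flatten_volume`."""
    data = flat.intensities
    nx, ny_out, nz = data.shape
    ny = info.original_ny
    out = np.empty((nx, ny, nz), dtype=data.dtype)
    for s in np.unique(info.shifts):
        sel = info.shifts == s
        off = info.pad_top + int(s)
        cols = np.where(sel)
        out[cols[0], :, cols[1]] = data[cols[0], off:off + ny, cols[1]]
    return OCTVolume(out, flat.spacing, flat.source_id)
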