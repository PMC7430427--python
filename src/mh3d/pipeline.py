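"""End-to-end orchestration: volume in, morphometry report out.

``segment_and_measure`` is the in-memory pipeline (surfaces -> flatten ->
LGDF segmentation -> curvature cut -> morphometry); ``run_pipeline`` wraps
it with file IO and a run manifest for the CLI.  ``phantom_suite`` builds
the seeded family of phantom shapes (cylinders, hourglasses, rotated
ellipses, tilted holes) used for parameter-recovery validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .morphometry import MorphometryReport, PlanarSection, measure_hole
from .oct_io import (HoleMask, OCTVolume, SurfaceMap, SurfaceParams,
                     VoxelSpacing, estimate_surfaces, flatten_volume,
                     read_spacing_metadata, read_tiff_stack, write_tiff_stack)
from .phantom import EllipseSection, PhantomSpec, generate_phantom
from .segmentation import (CutParams, LevelSetParams, curvature_surface_cut,
                           multiscale_segment)

__all__ = [
    "PipelineResult",
    "RunManifest",
    "segment_and_measure",
    "run_pipeline",
    "phantom_suite",
    "default_phantom_spec",
]


@dataclass
class PipelineResult:
    report: MorphometryReport
    sections: list[PlanarSection]
    mask: HoleMask                #: in the flattened frame (RPE constant)
    mask_original: HoleMask       #: mapped back to the input voxel grid
    rpe_level_um: float
    ilm_flat: SurfaceMap
    iteration_log: list[dict]


def segment_and_measure(volume: OCTVolume,
                        level_set: LevelSetParams | None = None,
                        cut: CutParams | None = None,
                        surface_params: SurfaceParams | None = None
                        ) -> PipelineResult:
    """Run the full analysis on an in-memory volume.

    Estimates the RPE/ILM surfaces, flattens the volume to the RPE,
    segments the hole with the multiscale LGDF level set, separates it
    from the vitreous with the curvature surface cut, and measures the
    complete 3D parameter set.
    """
    ls = level_set or LevelSetParams()
    rpe, ilm = estimate_surfaces(volume, surface_params)
    flat, ilm_flat, info = flatten_volume(volume, rpe, ilm)
    sp = volume.spacing
    level_um = info.rpe_level_index * sp.dy
    rpe_flat = SurfaceMap(np.full_like(rpe.y_um, level_um), "RPE", sp)
    mask, log = multiscale_segment(flat, ls, rpe_flat, ilm_flat)
    mask = curvature_surface_cut(mask, rpe_flat, ilm_flat, cut)
    report, sections = measure_hole(mask, level_um, ilm_flat)
    from .oct_io import unflatten_volume

    unflat = unflatten_volume(
        OCTVolume(mask.voxels.astype(np.uint8), sp, volume.source_id), info)
    mask_original = HoleMask(unflat.intensities > 0, sp)
    return PipelineResult(report=report, sections=sections, mask=mask,
                          mask_original=mask_original,
                          rpe_level_um=level_um, ilm_flat=ilm_flat,
                          iteration_log=log)


# ---------------------------------------------------------------------------
# manifest + file pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record written for every run, success or failure."""

    subcommand: str
    inputs: dict
    config: dict
    seed: int | None
    version: str
    started: str
    finished: str = ""
    stages: list[dict] = field(default_factory=list)
    status: str = "running"

    def stage(self, name: str, status: str, detail: str = "") -> None:
        self.stages.append({"stage": name, "status": status,
                            "detail": detail})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def write(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["config_hash"] = self.config_hash
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def json_default(obj):
    """Serialise numpy scalars/arrays that leak into report payloads."""
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _params_dict(obj) -> dict:
    return dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)


def report_to_frame(report: MorphometryReport, source_id: str = ""
                    ) -> pd.DataFrame:
    d = {"source_id": source_id}
    d.update(report.as_dict())
    return pd.DataFrame([d])


def sections_to_frame(sections: list[PlanarSection]) -> pd.DataFrame:
    return pd.DataFrame([{
        "height_um": s.height_um, "area_um2": s.area_um2,
        "feret_min_um": s.feret_min_um, "feret_max_um": s.feret_max_um,
        "angle_min_deg": s.angle_min_deg, "angle_max_deg": s.angle_max_deg,
        "cx_um": s.centroid_x_um, "cz_um": s.centroid_z_um,
        "n_pixels": s.n_pixels,
    } for s in sections])


def run_pipeline(folder: str | Path, out_dir: str | Path,
                 spacing: VoxelSpacing | None = None,
                 level_set: LevelSetParams | None = None,
                 cut: CutParams | None = None,
                 surface_params: SurfaceParams | None = None
                 ) -> tuple[MorphometryReport, RunManifest]:
    """File-level pipeline: TIFF folder in, report + mask + manifest out.

    ``spacing`` defaults to the sidecar ``metadata.txt`` inside the
    folder.  A stage failure aborts with the stage named in the manifest;
    partial outputs written so far are preserved.
    """
    folder = Path(folder)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ls = level_set or LevelSetParams()
    cp = cut or CutParams()
    sps = surface_params or SurfaceParams()
    manifest = RunManifest(
        subcommand="run",
        inputs={"folder": str(folder)},
        config={"level_set": _params_dict(ls), "cut": _params_dict(cp),
                "surfaces": _params_dict(sps),
                "spacing": _params_dict(spacing) if spacing else "metadata"},
        seed=None, version=__version__, started=_now())
    manifest_path = out / "manifest.json"

    def fail(stage: str, err: Exception):
        manifest.stage(stage, "failed", str(err))
        manifest.status = f"failed:{stage}"
        manifest.finished = _now()
        manifest.write(manifest_path)
        raise err

    try:
        if spacing is None:
            spacing, src = read_spacing_metadata(folder / "metadata.txt")
        volume = read_tiff_stack(folder, spacing)
        manifest.stage("read", "ok", f"shape={volume.shape}")
    except Exception as e:  # noqa: BLE001 - stage boundary
        fail("read", e)
    try:
        result = segment_and_measure(volume, ls, cp, sps)
        manifest.stage("segment+measure", "ok",
                       f"mask_voxels={result.mask.n_voxels}")
    except Exception as e:  # noqa: BLE001
        fail("segment", e)

    report_to_frame(result.report, volume.source_id).to_csv(
        out / "report.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(result.report.as_dict(), indent=2, sort_keys=True,
                   default=json_default) + "\n")
    sections_to_frame(result.sections).to_csv(out / "sections.csv",
                                              index=False)
    pd.DataFrame(result.iteration_log).to_csv(out / "iterations.csv",
                                              index=False)
    write_tiff_stack(result.mask, out / "mask", prefix="mask")
    manifest.stage("write", "ok", str(out))
    manifest.status = "ok"
    manifest.finished = _now()
    manifest.write(manifest_path)
    return result.report, manifest


# ---------------------------------------------------------------------------
# phantom suite
# ---------------------------------------------------------------------------

#: Desk-scale study geometry: the clinical macular-cube proportions
#: (768 x 496 x 49 at 5.47 x 3.87 x 30 um) downsampled laterally ~5x so a
#: full segmentation runs in seconds; Z keeps the clinical 30 um pitch.
DESK_NX, DESK_NY, DESK_NZ = 160, 120, 49
DESK_SPACING = VoxelSpacing(10.94, 7.74, 30.0)
DESK_ILM_UM = 150.0
DESK_RPE_UM = 450.0


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Canonical mid-size hourglass hole in the desk-scale geometry."""
    base = dict(
        nx=DESK_NX, ny=DESK_NY, nz=DESK_NZ, spacing=DESK_SPACING,
        ilm_depth_um=DESK_ILM_UM, rpe_depth_um=DESK_RPE_UM,
        base=EllipseSection(380.0, 330.0, 0.0),
        waist=EllipseSection(200.0, 170.0, 0.0),
        top=EllipseSection(300.0, 260.0, 0.0),
        waist_fraction=0.5, seed=seed)
    base.update(overrides)
    return PhantomSpec(**base)


def phantom_suite(n: int, seed: int = 0, speckle: float = 0.0
                  ) -> list[PhantomSpec]:
    """``n`` seeded phantom specs spanning the validation shape family.

    Cycles through cylinder, hourglass, rotated-ellipse and tilted
    archetypes with reproducible jitter on sizes, waist height, meridians
    and tilt.  Elliptical archetypes keep an axis ratio >= ~1.2 so their
    meridians are well defined.
    """
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    archetypes = ("cylinder", "hourglass", "ellipse", "tilted")
    for i in range(n):
        kind = archetypes[i % len(archetypes)]
        jit = lambda lo, hi: float(rng.uniform(lo, hi))  # noqa: E731
        common = dict(nx=DESK_NX, ny=DESK_NY, nz=DESK_NZ,
                      spacing=DESK_SPACING, ilm_depth_um=DESK_ILM_UM,
                      rpe_depth_um=DESK_RPE_UM, speckle=speckle,
                      seed=seed * 1000 + i)
        if kind == "cylinder":
            r = jit(180, 300)
            sec = EllipseSection(r, r, 0.0)
            specs.append(PhantomSpec(base=sec, waist=sec, top=sec,
                                     waist_fraction=0.5, **common))
        elif kind == "hourglass":
            rb = jit(300, 400)
            rw = jit(150, 220)
            rt = jit(220, 300)
            specs.append(PhantomSpec(
                base=EllipseSection(rb, rb * jit(0.8, 0.95)),
                waist=EllipseSection(rw, rw * jit(0.78, 0.92),
                                     jit(0, 180)),
                top=EllipseSection(rt, rt * jit(0.8, 0.95)),
                waist_fraction=jit(0.35, 0.6), **common))
        elif kind == "ellipse":
            th = jit(0, 180)
            ab, bb = jit(320, 400), jit(230, 280)
            aw, bw = jit(190, 240), jit(140, 170)
            at, bt = jit(250, 310), jit(180, 220)
            specs.append(PhantomSpec(
                base=EllipseSection(ab, bb, th),
                waist=EllipseSection(aw, bw, th + jit(-15, 15)),
                top=EllipseSection(at, bt, th + jit(-15, 15)),
                waist_fraction=jit(0.4, 0.6), **common))
        else:  # tilted
            r = jit(200, 280)
            ang = jit(0, 2 * np.pi)
            mag = jit(80, 150)
            specs.append(PhantomSpec(
                base=EllipseSection(r, r),
                waist=EllipseSection(r * jit(0.6, 0.8),
                                     r * jit(0.6, 0.8)),
                top=EllipseSection(r * jit(0.8, 1.0), r * jit(0.8, 1.0)),
                waist_fraction=jit(0.4, 0.6),
                tilt_x_um=mag * np.cos(ang), tilt_z_um=mag * np.sin(ang),
                **common))
    return specs


def run_phantom_suite(out_dir: str | Path, n: int, seed: int = 0,
                      speckle: float = 0.0) -> pd.DataFrame:
    """Generate ``n`` phantoms on disk: TIFF volumes, truth masks, truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(phantom_suite(n, seed, speckle)):
        volume, truth_mask, truth = generate_phantom(spec)
        vdir = out / f"phantom_{i:03d}"
        write_tiff_stack(volume, vdir / "volume")
        write_tiff_stack(truth_mask, vdir / "truth_mask")
        from .oct_io import write_spacing_metadata

        write_spacing_metadata(vdir / "volume" / "metadata.txt", spec.spacing,
                               volume.source_id)
        row = {"phantom": f"phantom_{i:03d}", "seed": spec.seed}
        row.update(truth.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "truth.csv", index=False)
    return df
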