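"""Pipeline orchestration: configuration, scene processing, run manifests.

Ties the stages together: simulate → segment → back-project → register →
reconstruct → volume → calibrate → fat mass → agreement.  Every run is
driven by a single :class:`PipelineConfig` (YAML round-trippable; all
randomness flows from its one seed) and produces a :class:`RunManifest`
recording the config snapshot, input digests, per-stage timings and
warnings, and every output file written.  Deterministic stages re-run under
an identical manifest reproduce identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraModel, default_rig
from .densitometry import fit_bv_calibration, predict_fat_mass, report_bv_error
from .errors import StageError
from .mesh import clean_mesh, mesh_volume, save_mesh
from .pointcloud import backproject, estimate_normals
from .poisson import reconstruct_surface
from .register import align_views
from .render import render_views
from .sceneio import read_scene, scene_paths
from .segmentation import apply_mask, clean_mask, exclude_platform, segment_body

log = logging.getLogger(__name__)

try:
    __version__ = version("bodyscan")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "VolumeEstimate",
    "run_pipeline",
    "process_scene_pair",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with documented defaults.

    Nested dicts keep the YAML layout flat and readable; see
    ``docs/methods.md`` for what each parameter does and why the default.
    """

    camera: dict = field(
        default_factory=lambda: {
            "distance_m": 1.9,       # camera-to-axis stand-off
            "height_m": 1.0,         # optical-centre height above platform
            "noise_sigma_mm": 0.0,   # depth noise (renderer)
            "dropout_rate": 0.0,     # depth dropout (renderer)
            "image_scale": 1.0,      # uniform intrinsics/raster scale
        }
    )
    platform_height_m: float = 0.05
    segmentation: dict = field(
        default_factory=lambda: {
            "threshold_policy": "otsu",
            "grow_tolerance_frac": 0.25,
            "open_radius_px": 1,
            "close_radius_px": 1,
            "min_component_px": 64,
            "platform_depth_offset_mm": 150.0,
        }
    )
    icp: dict = field(
        default_factory=lambda: {
            "max_iter": 100,
            "tol": 1e-8,
            "trim_frac": 0.1,
            "max_corr_dist_m": 0.015,
            # trust region: reject refinements beyond the rig's calibration
            # uncertainty (see register module docstring)
            "max_correction_m": 0.01,
            "max_correction_deg": 1.0,
        }
    )
    reconstruction: dict = field(
        default_factory=lambda: {"normal_k": 30, "poisson_depth": 8}
    )
    mesh: dict = field(
        default_factory=lambda: {"min_component_frac": 0.01, "smooth_iters": 3}
    )
    seed: int = 0
    output_dir: str = "bodyscan_out"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key '{k}'")
            current = getattr(cfg, k)
            if isinstance(current, dict):
                unknown = set(v) - set(current)
                if unknown:
                    raise KeyError(f"unknown config keys {sorted(unknown)} under '{k}'")
                current.update(v)
            else:
                setattr(cfg, k, v)
        return cfg

    def rig(self) -> tuple[CameraModel, CameraModel]:
        c = self.camera
        front, back = default_rig(
            distance_m=c["distance_m"],
            height_m=c["height_m"],
            noise_sigma_mm=c["noise_sigma_mm"],
            dropout_rate=c["dropout_rate"],
        )
        s = float(c.get("image_scale", 1.0))
        if s != 1.0:
            front = _scaled_camera(front, s)
            back = _scaled_camera(back, s)
        return front, back


def _scaled_camera(cam: CameraModel, s: float) -> CameraModel:
    return dataclasses.replace(
        cam,
        fx=cam.fx * s,
        fy=cam.fy * s,
        cx=cam.cx * s,
        cy=cam.cy * s,
        width=int(round(cam.width * s)),
        height=int(round(cam.height * s)),
    )


@dataclass
class VolumeEstimate:
    """Raw (and, once calibrated, fitted) body volume for one scan."""

    raw_liters: float
    fitted_liters: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.raw_liters <= 0:
            raise ValueError("raw volume must be positive")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    package_version: str = __version__
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stages: list = field(default_factory=list)    # {name, input_id, duration_s, warnings}
    results: dict = field(default_factory=dict)

    def add_stage(self, name, input_id, duration_s, warns):
        self.stages.append(
            {
                "name": name,
                "input_id": input_id,
                "duration_s": float(duration_s),
                "warnings": [str(w) for w in warns],
            }
        )

    def comparable(self) -> dict:
        """Manifest content minus timings (for reproducibility checks)."""
        d = dataclasses.asdict(self)
        for s in d["stages"]:
            s.pop("duration_s", None)
        return d

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _Stage:
    """Context helper: times a stage, collects warnings, wraps errors."""

    def __init__(self, manifest: RunManifest, name: str, input_id: str):
        self.manifest = manifest
        self.name = name
        self.input_id = input_id

    def __enter__(self):
        self._t0 = time.perf_counter()
        self._wctx = warnings.catch_warnings(record=True)
        self._warns = self._wctx.__enter__()
        warnings.simplefilter("always")
        return self

    def __exit__(self, exc_type, exc, tb):
        self._wctx.__exit__(None, None, None)
        self.manifest.add_stage(
            self.name,
            self.input_id,
            time.perf_counter() - self._t0,
            [w.message for w in self._warns],
        )
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, self.input_id, exc) from exc
        return False


def process_scene_pair(
    anterior_stem,
    posterior_stem,
    config: PipelineConfig | None = None,
    manifest: RunManifest | None = None,
    input_id: str = "scene",
):
    """Reconstruct one scan: two written scene views → (VolumeEstimate, BodyMesh).

    *anterior_stem*/*posterior_stem* are the path stems used by
    :func:`bodyscan.sceneio.write_scene`.
    """
    config = config or PipelineConfig()
    manifest = manifest or RunManifest(config=dataclasses.asdict(config))

    with _Stage(manifest, "read", input_id):
        renders = []
        for stem in (anterior_stem, posterior_stem):
            for kind, p in scene_paths(stem).items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing {kind} file: {p}")
                manifest.inputs[str(p)] = _digest(p)
            renders.append(read_scene(stem))
    return _reconstruct_from_renders(renders, config, manifest, input_id)


def _reconstruct_from_renders(renders, config, manifest, input_id):
    seg = config.segmentation
    clouds = {}
    with _Stage(manifest, "segment", input_id):
        for r in renders:
            mask = segment_body(
                r.ir,
                threshold_policy=seg["threshold_policy"],
                grow_tolerance_frac=seg["grow_tolerance_frac"],
                view=r.view,
            )
            mask = exclude_platform(
                mask, r.depth, depth_offset_mm=seg["platform_depth_offset_mm"], ir=r.ir
            )
            mask = clean_mask(
                mask,
                open_radius_px=seg["open_radius_px"],
                close_radius_px=seg["close_radius_px"],
                min_component_px=seg["min_component_px"],
            )
            md = apply_mask(
                r.depth,
                mask,
                near_mm=r.camera.near_m * 1000.0,
                far_mm=r.camera.far_m * 1000.0,
            )
            clouds[r.view] = estimate_normals(
                backproject(md, r.camera), k=config.reconstruction["normal_k"]
            )
    with _Stage(manifest, "register", input_id):
        icp = config.icp
        transform, merged, rms = align_views(
            clouds["anterior"],
            clouds["posterior"],
            max_iter=icp["max_iter"],
            tol=icp["tol"],
            trim_frac=icp["trim_frac"],
            max_corr_dist_m=icp["max_corr_dist_m"],
            max_correction_m=icp["max_correction_m"],
            max_correction_deg=icp["max_correction_deg"],
        )
    with _Stage(manifest, "reconstruct", input_id):
        mesh = reconstruct_surface(
            merged,
            normal_k=config.reconstruction["normal_k"],
            poisson_depth=config.reconstruction["poisson_depth"],
        )
        mesh = clean_mesh(
            mesh,
            min_component_frac=config.mesh["min_component_frac"],
            smooth_iters=config.mesh["smooth_iters"],
        )
    with _Stage(manifest, "volume", input_id):
        raw = mesh_volume(mesh)
    estimate = VolumeEstimate(
        raw_liters=raw,
        provenance={
            "input_id": input_id,
            "icp_rms_m": rms,
            "icp_correction_deg": transform.rotation_angle_deg(),
            "n_points": len(merged),
            "n_faces": len(mesh.faces),
        },
    )
    return estimate, mesh


def run_pipeline(
    config: PipelineConfig,
    scene_pairs: list | None = None,
    phantoms: list | None = None,
    reference_bv_l: list | None = None,
    subjects: list | None = None,
    write_meshes: bool = False,
) -> tuple[RunManifest, dict]:
    """Run the full pipeline over scans and produce a JSON-able report.

    Scans come either from *scene_pairs* (list of ``(anterior_stem,
    posterior_stem)``) or from *phantoms* (list of :class:`Phantom`), which
    are simulated first with the config's rig and seed.  When reference BVs
    are given (directly, or implicitly as phantom ground truth), the raw
    volumes are calibrated against them and the error summary reported; when
    *subjects* (:class:`SubjectRecord`) are given as well, fat mass is
    predicted per subject from the fitted volumes.

    Returns ``(manifest, report)``; the report is also written to
    ``<output_dir>/report.json`` and the manifest to
    ``<output_dir>/manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    front, back = config.rig()

    jobs = []
    if scene_pairs is not None:
        jobs = [("scene", pair) for pair in scene_pairs]
    elif phantoms is not None:
        if reference_bv_l is None:
            reference_bv_l = [p.reference_volume_liters for p in phantoms]
        for i, ph in enumerate(phantoms):
            jobs.append(("phantom", (ph, i)))
    else:
        raise ValueError("provide scene_pairs or phantoms")

    estimates = []
    for kind, payload in jobs:
        if kind == "phantom":
            ph, i = payload
            input_id = f"{ph.label}#{i}"
            with _Stage(manifest, "simulate", input_id):
                ant, post = render_views(
                    ph, front, back,
                    platform_height_m=config.platform_height_m,
                    seed=int(config.seed) + i,
                )
            est, mesh = _reconstruct_from_renders([ant, post], config, manifest, input_id)
        else:
            input_id = str(payload[0])
            est, mesh = process_scene_pair(
                payload[0], payload[1], config, manifest, input_id
            )
        if write_meshes:
            mpath = out / f"{Path(str(est.provenance['input_id'])).name}_body.ply"
            save_mesh(mesh, mpath)
            manifest.outputs[str(mpath)] = _digest(mpath)
        estimates.append(est)

    report: dict = {
        "n_scans": len(estimates),
        "raw_bv_l": [e.raw_liters for e in estimates],
    }
    if reference_bv_l is not None:
        ref = [float(v) for v in reference_bv_l]
        report["reference_bv_l"] = ref
        with _Stage(manifest, "calibrate", "cohort"):
            raw = [e.raw_liters for e in estimates]
            report["raw_error"] = report_bv_error(raw, ref)
            if len(raw) >= 3 and np.ptp(raw) > 0:
                cal = fit_bv_calibration(raw, ref)
                fitted = [cal.slope * r + cal.intercept for r in raw]
                for e, f in zip(estimates, fitted):
                    e.fitted_liters = f
                report["calibration"] = {
                    "slope": cal.slope,
                    "intercept_l": cal.intercept,
                    "residual_sd_l": cal.residual_sd,
                    "n_fit": cal.n_fit,
                }
                report["fitted_bv_l"] = fitted
                report["fitted_error"] = report_bv_error(fitted, ref)
    if subjects is not None:
        with _Stage(manifest, "fat_mass", "cohort"):
            fms = []
            for subj, e in zip(subjects, estimates):
                bv = e.fitted_liters if e.fitted_liters is not None else e.raw_liters
                fms.append(predict_fat_mass(subj, bv).fm_kg)
            report["fat_mass_kg"] = fms

    rpath = out / "report.json"
    rpath.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest.outputs[str(rpath)] = _digest(rpath)
    manifest.results = {
        "raw_bv_l": report["raw_bv_l"],
        "fitted_bv_l": report.get("fitted_bv_l"),
    }
    manifest.write(out / "manifest.json")
    return manifest, report
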