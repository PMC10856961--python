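"""Scene file formats: 16-bit depth PNG (mm), 8-bit IR PNG, YAML camera sidecar.

File layout for a written view is ``<stem>_ir.png``, ``<stem>_depth.png`` and
``<stem>_camera.yaml``; read-back round-trips the raster data bit-exactly and
the camera intrinsics to full float precision.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .camera import CameraModel
from .errors import DepthRangeError
from .render import SceneRender

__all__ = ["write_scene", "read_scene", "scene_paths"]


def scene_paths(path, view: str | None = None) -> dict[str, Path]:
    stem = Path(path)
    if view:
        stem = stem.with_name(f"{stem.name}_{view}")
    return {
        "ir": stem.with_name(stem.name + "_ir.png"),
        "depth": stem.with_name(stem.name + "_depth.png"),
        "camera": stem.with_name(stem.name + "_camera.yaml"),
    }


def write_scene(render: SceneRender, path) -> dict[str, Path]:
    """Write one view to ``<path>_{ir,depth,camera}.*``; returns the paths.

    Depth must fit the 16-bit millimetre range; values above 65535 mm raise
    :class:`DepthRangeError` (they cannot round-trip through the PNG).
    """
    depth = np.asarray(render.depth)
    if depth.max(initial=0) > 65535 or depth.min(initial=0) < 0:
        raise DepthRangeError("depth exceeds the 16-bit millimetre range")
    paths = scene_paths(path)
    paths["ir"].parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(paths["ir"], np.asarray(render.ir, dtype=np.uint8))
    iio.imwrite(paths["depth"], depth.astype(np.uint16))
    sidecar = {
        "view": render.view,
        "seed": int(render.seed),
        "camera": render.camera.to_dict(),
    }
    paths["camera"].write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return paths


def read_scene(path) -> SceneRender:
    """Read a view written by :func:`write_scene`.

    The ground-truth side channels are not serialized; the returned render
    carries the noisy depth as its own ``true_depth_mm`` and body-labels
    derived from nothing (all background) — downstream stages only use
    ``ir``/``depth``/``camera``.
    """
    paths = scene_paths(path)
    ir = np.asarray(iio.imread(paths["ir"]))
    depth = np.asarray(iio.imread(paths["depth"])).astype(np.uint16)
    sidecar = yaml.safe_load(paths["camera"].read_text())
    cam = CameraModel.from_dict(sidecar["camera"])
    return SceneRender(
        ir=ir,
        depth=depth,
        view=sidecar["view"],
        camera=cam,
        seed=int(sidecar.get("seed", 0)),
        true_depth_mm=depth.astype(float),
        labels=np.zeros_like(depth, dtype=np.uint8),
    )
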