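"""Ray-cast rendering of the two-view IR + depth acquisition.

Each of the two opposed depth cameras produces an IR reflectance image and a
z-depth image of the standing phantom on its reflective platform, mimicking
the four images acquired per subject.  Rendering is a pure function of
(phantom, cameras, platform, seed): identical calls give bit-identical
frames.

The IR model is two-level reflectance — body bright, platform brighter
(high-reflectance paint), background dark — which is all the downstream
threshold/region-growth segmentation requires.  Depth noise is Gaussian in
millimetres followed by random dropout to 0, applied per camera from
independent substreams of the scene seed.

Ground truth (noiseless depth, per-pixel part labels, the exact body-hit
mask) rides along on the :class:`SceneRender` for oracle use in tests; it is
never written to the scene files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import CameraModel
from .errors import EmptyRenderError
from .phantoms import Phantom, platform_primitive

__all__ = ["SceneRender", "render_views", "IR_BACKGROUND", "IR_BODY", "IR_PLATFORM"]

IR_BACKGROUND = 6
IR_BODY = 200
IR_PLATFORM = 245

LABEL_BACKGROUND = 0
LABEL_BODY = 1
LABEL_PLATFORM = 2


@dataclass
class SceneRender:
    """One rendered view: IR + depth rasters plus ground-truth side channels."""

    ir: np.ndarray          # (H, W) uint8
    depth: np.ndarray       # (H, W) uint16, z-depth in mm, 0 = invalid
    view: str               # "anterior" | "posterior"
    camera: CameraModel
    seed: int
    true_depth_mm: np.ndarray  # (H, W) float, noiseless z-depth, 0 = no hit
    labels: np.ndarray         # (H, W) uint8: 0 bg, 1 body, 2 platform

    def __post_init__(self):
        if self.ir.shape != self.depth.shape:
            raise ValueError("ir and depth dimensions differ")
        if self.view not in ("anterior", "posterior"):
            raise ValueError(f"bad view label '{self.view}'")

    @property
    def body_hit_mask(self) -> np.ndarray:
        """Exact silhouette oracle: pixels whose ray hits the phantom."""
        return self.labels == LABEL_BODY


def _render_one(
    phantom: Phantom,
    cam: CameraModel,
    platform,
    view: str,
    rng: np.random.Generator,
    seed: int,
) -> SceneRender:
    origin, dirs = cam.pixel_rays_world()
    flat = dirs.reshape(-1, 3)
    t_body = np.full(flat.shape[0], np.inf)
    for part in phantom.parts:
        t_body = np.minimum(t_body, part.ray_t(origin, flat))
    t_plat = platform.ray_t(origin, flat) if platform is not None else np.full_like(t_body, np.inf)

    t = np.minimum(t_body, t_plat)
    labels = np.where(
        np.isinf(t), LABEL_BACKGROUND, np.where(t_body <= t_plat, LABEL_BODY, LABEL_PLATFORM)
    ).astype(np.uint8)
    # clip to the camera's working range
    valid = np.isfinite(t) & (t >= cam.near_m) & (t <= cam.far_m)
    labels[~valid] = LABEL_BACKGROUND

    true_mm = np.where(valid, t * 1000.0, 0.0)
    ir = np.full(flat.shape[0], IR_BACKGROUND, dtype=np.uint8)
    ir[labels == LABEL_BODY] = IR_BODY
    ir[labels == LABEL_PLATFORM] = IR_PLATFORM

    depth = true_mm.copy()
    if cam.noise_sigma_mm > 0:
        depth[valid] += rng.normal(0.0, cam.noise_sigma_mm, size=int(valid.sum()))
    if cam.dropout_rate > 0:
        drop = rng.random(int(valid.sum())) < cam.dropout_rate
        dv = depth[valid]
        dv[drop] = 0.0
        depth[valid] = dv
    depth = np.clip(np.rint(depth), 0, 65535).astype(np.uint16)

    H, W = cam.height, cam.width
    return SceneRender(
        ir=ir.reshape(H, W),
        depth=depth.reshape(H, W),
        view=view,
        camera=cam,
        seed=seed,
        true_depth_mm=true_mm.reshape(H, W),
        labels=labels.reshape(H, W),
    )


def render_views(
    phantom: Phantom,
    front: CameraModel,
    back: CameraModel,
    platform_height_m: float = 0.05,
    seed: int = 0,
) -> tuple[SceneRender, SceneRender]:
    """Render the anterior (front camera) and posterior (back camera) views.

    *platform_height_m* of 0 disables the platform.  Raises
    :class:`EmptyRenderError` when the phantom is outside both frusta.
    """
    if platform_height_m < 0:
        raise ValueError("platform_height_m must be >= 0")
    platform = platform_primitive(platform_height_m) if platform_height_m > 0 else None
    rng_a = np.random.default_rng([int(seed), 0])
    rng_p = np.random.default_rng([int(seed), 1])
    anterior = _render_one(phantom, front, platform, "anterior", rng_a, seed)
    posterior = _render_one(phantom, back, platform, "posterior", rng_p, seed)
    if not anterior.body_hit_mask.any() and not posterior.body_hit_mask.any():
        raise EmptyRenderError("phantom outside both camera frusta")
    return anterior, posterior
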