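"""Pinhole depth-camera model and rigid poses.

Conventions
-----------
* World frame: right-handed, +y up, origin at the centre of the standing
  platform.  The default rig places two cameras at ``(0, 1.0, ±1.9)`` m with a
  horizontal gaze, i.e. about 1.9 m in front of and behind the subject.
* Camera frame: +z along the optical axis (into the scene), +x to the image
  right, +y down (so image row ``v`` grows along camera +y).
* Depth images store z-depth — the distance along the optical axis — in
  integer millimetres, with 0 marking an invalid pixel.

The intrinsics default to published Kinect-v2-class values (512 x 424 px,
focal 365 px), the sensor family the acquisition geometry emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RigidTransform", "CameraModel", "look_at", "default_rig"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x' = rotation @ x + translation`` (metres)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal (tol 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def look_at(eye, target, world_up=(0.0, 1.0, 0.0)) -> RigidTransform:
    """Camera-from-world pose for a camera at *eye* looking at *target*.

    Uses the y-down camera convention: the returned rotation maps world
    vectors into a frame whose +z axis points from *eye* to *target* and whose
    +y axis points opposite *world_up* (image rows grow downwards).
    """
    eye = np.asarray(eye, dtype=float)
    target = np.asarray(target, dtype=float)
    fwd = target - eye
    n = np.linalg.norm(fwd)
    if n == 0:
        raise ValueError("eye and target coincide")
    z_c = fwd / n
    up = np.asarray(world_up, dtype=float)
    x_c = np.cross(z_c, up)
    nx = np.linalg.norm(x_c)
    if nx < 1e-12:
        raise ValueError("gaze direction parallel to world up")
    x_c /= nx
    y_c = np.cross(z_c, x_c)
    R_wc = np.column_stack([x_c, y_c, z_c])  # camera axes in world coords
    R_cw = R_wc.T
    return RigidTransform(R_cw, -R_cw @ eye)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics plus rigid pose of one depth/IR camera.

    ``pose`` is the camera-from-world transform.  ``noise_sigma_mm`` and
    ``dropout_rate`` describe the sensor's depth noise model and are consumed
    by the renderer only.
    """

    fx: float = 365.0
    fy: float = 365.0
    cx: float = 256.0
    cy: float = 212.0
    width: int = 512
    height: int = 424
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    near_m: float = 0.5
    far_m: float = 4.5
    noise_sigma_mm: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise_sigma_mm must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not (0 < self.near_m < self.far_m):
            raise ValueError("need 0 < near < far")

    @property
    def origin_world(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        inv = self.pose.inverse()
        return inv.translation

    def pixel_rays_world(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray origins/directions in the world frame.

        Directions are scaled so that the parameter ``t`` along each ray is
        the camera z-depth in metres.  Returns ``(origin (3,), dirs (H,W,3))``.
        """
        u = np.arange(self.width, dtype=float)
        v = np.arange(self.height, dtype=float)
        uu, vv = np.meshgrid(u, v)
        d_cam = np.stack(
            [(uu - self.cx) / self.fx, (vv - self.cy) / self.fy, np.ones_like(uu)],
            axis=-1,
        )
        R_wc = self.pose.rotation.T
        dirs = d_cam @ R_wc.T
        return self.origin_world, dirs

    def with_pose(self, pose: RigidTransform) -> "CameraModel":
        return replace(self, pose=pose)

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
            "near_m": self.near_m,
            "far_m": self.far_m,
            "noise_sigma_mm": self.noise_sigma_mm,
            "dropout_rate": self.dropout_rate,
            "rotation": self.pose.rotation.tolist(),
            "translation": self.pose.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        pose = RigidTransform(np.array(d["rotation"]), np.array(d["translation"]))
        keys = (
            "fx", "fy", "cx", "cy", "width", "height",
            "near_m", "far_m", "noise_sigma_mm", "dropout_rate",
        )
        return cls(pose=pose, **{k: d[k] for k in keys if k in d})


def default_rig(
    distance_m: float = 1.9,
    height_m: float = 1.0,
    noise_sigma_mm: float = 0.0,
    dropout_rate: float = 0.0,
) -> tuple[CameraModel, CameraModel]:
    """Front and back cameras of the two-view acquisition geometry.

    Each camera sits *distance_m* from the vertical axis through the platform
    centre at *height_m* above the platform, gazing horizontally, so the two
    optical axes are anti-parallel (the back view is the front view rotated
    180 deg about the vertical axis).
    """
    front = CameraModel(
        pose=look_at((0.0, height_m, -distance_m), (0.0, height_m, 0.0)),
        noise_sigma_mm=noise_sigma_mm,
        dropout_rate=dropout_rate,
    )
    back = CameraModel(
        pose=look_at((0.0, height_m, distance_m), (0.0, height_m, 0.0)),
        noise_sigma_mm=noise_sigma_mm,
        dropout_rate=dropout_rate,
    )
    return front, back
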