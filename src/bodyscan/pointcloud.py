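"""Back-projection of masked depth images to world-frame point clouds.

A valid pixel ``(u, v)`` with z-depth ``z`` maps to camera coordinates
``x = (u - cx) z / fx``, ``y = (v - cy) z / fy``, ``z``, and then to the
world frame through the inverse camera pose.  Each point remembers the
camera centre it was seen from, which later gives an exact outward
orientation for its surface normal (a depth sensor only sees surface
elements that face it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .camera import CameraModel
from .errors import EmptyCloudError
from .segmentation import MaskedDepth

__all__ = ["PointCloud", "backproject", "estimate_normals", "merge_clouds"]


@dataclass
class PointCloud:
    """N x 3 points in metres (world frame) with optional normals."""

    points: np.ndarray
    normals: np.ndarray | None = None
    view: str | None = None
    view_origins: np.ndarray | None = None  # camera centre per point

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(pts) < 1:
            raise EmptyCloudError("point cloud is empty")
        if not np.isfinite(pts).all():
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if self.view_origins is not None:
            self.view_origins = np.asarray(self.view_origins, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def transformed(self, transform) -> "PointCloud":
        return PointCloud(
            transform.apply(self.points),
            None if self.normals is None else self.normals @ transform.rotation.T,
            view=self.view,
            view_origins=None
            if self.view_origins is None
            else transform.apply(self.view_origins),
        )


def backproject(md: MaskedDepth, cam: CameraModel) -> PointCloud:
    """Lift every valid masked-depth pixel into a world-frame 3D point."""
    depth = np.asarray(md.depth_mm, dtype=float)
    vv, uu = np.nonzero(depth > 0)
    if len(vv) == 0:
        raise EmptyCloudError("masked depth has no valid pixel")
    z = depth[vv, uu] / 1000.0
    x = (uu - cam.cx) * z / cam.fx
    y = (vv - cam.cy) * z / cam.fy
    p_cam = np.column_stack([x, y, z])
    world_from_cam = cam.pose.inverse()
    pts = world_from_cam.apply(p_cam)
    origin = cam.origin_world
    return PointCloud(
        pts,
        view=md.view,
        view_origins=np.broadcast_to(origin, pts.shape).copy(),
    )


def estimate_normals(cloud: PointCloud, k: int = 30) -> PointCloud:
    """PCA normals from *k* nearest neighbours, oriented outward.

    Orientation: toward the recording camera when the cloud carries per-point
    view origins (exact for 2.5D depth data); otherwise away from the cloud
    centroid followed by a consistency sweep over the k-NN graph.
    """
    pts = cloud.points
    k = min(k, len(pts))
    if k < 3:
        raise ValueError("need at least 3 neighbours for normal estimation")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    nbrs = pts[idx]  # (N, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # eigenvector of the smallest eigenvalue

    if cloud.view_origins is not None:
        toward = cloud.view_origins - pts
        flip = np.einsum("ij,ij->i", normals, toward) < 0
        normals[flip] *= -1
    else:
        outward = pts - cloud.centroid
        flip = np.einsum("ij,ij->i", normals, outward) < 0
        normals[flip] *= -1
        normals = _propagate_orientation(pts, normals, idx)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.clip(norms, 1e-30, None)
    return PointCloud(pts, normals, view=cloud.view, view_origins=cloud.view_origins)


def _propagate_orientation(pts, normals, idx) -> np.ndarray:
    """Greedy BFS over the k-NN graph flipping normals that disagree with an
    already-visited neighbour; seeded at the point farthest from the centroid
    (whose away-from-centroid orientation is most trustworthy)."""
    n = len(pts)
    out = normals.copy()
    seen = np.zeros(n, dtype=bool)
    seed = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    stack = [seed]
    seen[seed] = True
    while stack:
        i = stack.pop()
        for j in idx[i]:
            if not seen[j]:
                if out[j] @ out[i] < 0:
                    out[j] = -out[j]
                seen[j] = True
                stack.append(int(j))
    return out


def merge_clouds(*clouds: PointCloud) -> PointCloud:
    """Concatenate clouds; normals/origins are kept only if all carry them."""
    pts = np.vstack([c.points for c in clouds])
    normals = None
    if all(c.normals is not None for c in clouds):
        normals = np.vstack([c.normals for c in clouds])
    origins = None
    if all(c.view_origins is not None for c in clouds):
        origins = np.vstack([c.view_origins for c in clouds])
    return PointCloud(pts, normals, view="merged", view_origins=origins)
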