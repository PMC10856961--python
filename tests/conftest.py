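"""Shared fixtures: phantoms, rendered scenes, segmented clouds.

Everything is generated programmatically; heavy artefacts are module- or
session-scoped so the geometry suite renders each scene once.
"""

from __future__ import annotations

import numpy as np
import pytest

from bodyscan.camera import default_rig
from bodyscan.phantoms import humanoid_phantom, make_phantom
from bodyscan.pointcloud import backproject, estimate_normals
from bodyscan.render import render_views
from bodyscan.segmentation import apply_mask, clean_mask, exclude_platform, segment_body


@pytest.fixture(scope="session")
def humanoid():
    """Standing-adult phantom with a 4 mm voxel ground-truth volume."""
    return humanoid_phantom(voxel_resolution_m=0.004)


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def noiseless_scene(humanoid, rig):
    """Anterior/posterior renders of the humanoid at zero sensor noise."""
    front, back = rig
    return render_views(humanoid, front, back, seed=11)


@pytest.fixture(scope="session")
def segmented_clouds(noiseless_scene, rig):
    """World-frame clouds with normals for both views of the noiseless scene."""
    front, back = rig
    clouds = {}
    for render, cam in zip(noiseless_scene, (front, back)):
        mask = segment_body(render.ir, view=render.view)
        mask = exclude_platform(mask, render.depth, ir=render.ir)
        mask = clean_mask(mask, open_radius_px=0, close_radius_px=0)
        md = apply_mask(render.depth, mask)
        clouds[render.view] = estimate_normals(backproject(md, cam))
    return clouds


@pytest.fixture(scope="session")
def sphere_cloud():
    """10k noiseless points with exact normals on a sphere of radius 0.1 m."""
    rng = np.random.default_rng(42)
    v = rng.normal(size=(10000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * 0.1, v  # points, outward normals


@pytest.fixture
def sphere_phantom():
    return make_phantom([{"kind": "sphere", "dims": [0.1], "center": [0.0, 1.0, 0.0]}])
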