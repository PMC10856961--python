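"""Surface reconstruction and mesh volume: analytic oracles and invariants."""

import numpy as np
import pytest
import trimesh

from bodyscan.camera import RigidTransform
from bodyscan.errors import (
    NonWatertightError,
    ReconstructionError,
    VolumeUndefinedError,
)
from bodyscan.mesh import BodyMesh, clean_mesh, load_mesh, mesh_volume, save_mesh
from bodyscan.pointcloud import PointCloud, merge_clouds
from bodyscan.poisson import reconstruct_surface
from bodyscan.register import align_views

SPHERE_L = 4.0 / 3.0 * np.pi * 0.1**3 * 1000.0


def unit_cube_mesh():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return BodyMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


class TestMeshVolume:
    def test_unit_cube_exactly_1000_liters(self):
        assert mesh_volume(unit_cube_mesh()) == 1000.0

    def test_icosphere_within_half_percent(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=0.1)
        vol = mesh_volume(BodyMesh(np.asarray(ico.vertices), np.asarray(ico.faces)))
        assert vol == pytest.approx(SPHERE_L, rel=0.005)

    def test_flipped_face_is_undefined(self):
        cube = unit_cube_mesh()
        faces = cube.faces.copy()
        faces[0] = faces[0][::-1]
        with pytest.raises(VolumeUndefinedError):
            mesh_volume(BodyMesh(cube.vertices, faces))

    def test_open_mesh_is_undefined(self):
        cube = unit_cube_mesh()
        with pytest.raises(VolumeUndefinedError):
            mesh_volume(BodyMesh(cube.vertices, cube.faces[:-1]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_invariance(self, seed):
        """Volume is invariant under rigid motion to 1e-9 relative."""
        rng = np.random.default_rng(seed)
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        th = rng.uniform(0, np.pi)
        K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
        T = RigidTransform(R, rng.normal(size=3))
        cube = unit_cube_mesh()
        moved = cube.transformed(T)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(cube), rel=1e-9)


class TestReconstruct:
    def test_sphere_cloud_watertight_within_2pct(self, sphere_cloud):
        pts, normals = sphere_cloud
        mesh = reconstruct_surface(PointCloud(pts, normals), poisson_depth=7)
        assert mesh.watertight
        assert mesh_volume(mesh) == pytest.approx(SPHERE_L, rel=0.02)

    def test_refinement_does_not_worsen_sphere(self, sphere_cloud):
        """On the convex noiseless sphere, raising the reconstruction depth
        one step never increases the volume error (until the grid outresolves
        the 10k-point sampling)."""
        pts, normals = sphere_cloud
        cloud = PointCloud(pts, normals)
        errs = []
        for depth in (5, 6, 7):
            vol = mesh_volume(reconstruct_surface(cloud, poisson_depth=depth))
            errs.append(abs(vol - SPHERE_L) / SPHERE_L)
        assert errs[1] <= errs[0] + 1e-12
        assert errs[2] <= errs[1] + 1e-12

    def test_estimated_normals_path(self, sphere_cloud):
        """Without supplied normals the camera-oriented PCA estimate is used."""
        pts, _ = sphere_cloud
        cloud = PointCloud(pts, view_origins=pts * 30.0)
        vol = mesh_volume(reconstruct_surface(cloud, poisson_depth=6))
        assert vol == pytest.approx(SPHERE_L, rel=0.02)

    def test_collinear_points_raise(self):
        t = np.linspace(0, 1, 300)
        pts = np.column_stack([t, t, t])
        with pytest.raises(ReconstructionError):
            reconstruct_surface(PointCloud(pts))

    def test_tiny_cloud_raises(self):
        with pytest.raises(ReconstructionError):
            reconstruct_surface(PointCloud(np.random.default_rng(0).normal(size=(50, 3))))

    def test_two_view_humanoid_watertight_single_component(self, segmented_clouds):
        _, merged, _ = align_views(
            segmented_clouds["anterior"],
            segmented_clouds["posterior"],
            max_correction_m=0.01,
            max_correction_deg=1.0,
        )
        mesh = reconstruct_surface(merged, poisson_depth=8)
        assert mesh.watertight
        assert len(mesh.to_trimesh().split(only_watertight=False)) == 1


class TestCleanMesh:
    def test_floating_component_removed_volume_kept(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.1)
        cube = trimesh.creation.box(extents=(0.005, 0.005, 0.005))
        cube.apply_translation([0.5, 0.5, 0.5])
        combo = trimesh.util.concatenate([sphere, cube])
        mesh = BodyMesh(np.asarray(combo.vertices), np.asarray(combo.faces))
        cleaned = clean_mesh(mesh, min_component_frac=0.01, smooth_iters=0)
        assert mesh_volume(cleaned) == pytest.approx(
            mesh_volume(BodyMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))),
            rel=1e-9,
        )

    def test_identity_when_nothing_to_do(self):
        mesh = unit_cube_mesh()
        out = clean_mesh(mesh, smooth_iters=0)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_hole_filled_volume_preserved(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.1)
        vol0 = mesh_volume(BodyMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces)))
        holed = BodyMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces)[1:])
        fixed = clean_mesh(holed, smooth_iters=0)
        assert fixed.watertight
        assert mesh_volume(fixed) == pytest.approx(vol0, rel=0.001)

    def test_smoothing_changes_volume_below_1pct(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=0.1)
        mesh = BodyMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))
        smoothed = clean_mesh(mesh, smooth_iters=10)
        assert mesh_volume(smoothed) == pytest.approx(mesh_volume(mesh), rel=0.01)

    def test_unclosable_mesh_raises(self):
        # a lone triangle cannot be closed into a solid
        tri = BodyMesh(
            np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]), np.array([[0, 1, 2]])
        )
        with pytest.raises(NonWatertightError):
            clean_mesh(tri, smooth_iters=0)


def test_ply_roundtrip(tmp_path):
    mesh = unit_cube_mesh()
    for ascii_ply in (False, True):
        path = save_mesh(mesh, tmp_path / f"cube_{ascii_ply}.ply", ascii_ply=ascii_ply)
        back = load_mesh(path)
        assert mesh_volume(back) == pytest.approx(1000.0, rel=1e-9)
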