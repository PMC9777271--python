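"""Domain types, rigid transforms and file round-trips."""

import numpy as np
import pytest

from breastar.core import (
    BinaryVolume,
    InvariantError,
    PointSet,
    RigidTransform,
    ScalarVolume,
    TriangleMesh,
    apply_transform,
    compose,
    voxel_to_world,
)
from breastar.io import (
    FormatError,
    read_mesh,
    read_point_set,
    read_volume,
    write_mesh,
    write_point_set,
    write_volume,
)


class TestRigidTransform:
    def test_identity_leaves_input_unchanged(self):
        t = RigidTransform.identity()
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 7.0]])
        assert np.allclose(t.apply(pts), pts)

    def test_pure_translation(self):
        t = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        assert np.allclose(t.apply(np.zeros(3)), [1.0, 2.0, 3.0])

    def test_z_rotation_quarter_turn(self):
        t = RigidTransform.from_axis_angle([0, 0, 1], 90.0)
        assert np.allclose(t.apply(np.array([1.0, 0.0, 0.0])), [0.0, 1.0, 0.0], atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(InvariantError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))

    def test_reflection_rejected(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InvariantError, match="proper"):
            RigidTransform(refl, np.zeros(3))

    def test_compose_matches_homogeneous_matrix_product(self, rng):
        for _ in range(10):
            a = RigidTransform.from_axis_angle(rng.normal(size=3), rng.uniform(-180, 180),
                                               rng.normal(size=3) * 10)
            b = RigidTransform.from_axis_angle(rng.normal(size=3), rng.uniform(-180, 180),
                                               rng.normal(size=3) * 10)
            expected = a.as_matrix() @ b.as_matrix()
            assert np.allclose(compose(a, b).as_matrix(), expected, atol=1e-9)

    def test_compose_with_inverse_is_identity(self, rng):
        t = RigidTransform.from_axis_angle([1, 2, 3], 37.0, [4.0, -5.0, 6.0])
        ident = compose(t, t.inverse())
        assert np.allclose(ident.as_matrix(), np.eye(4), atol=1e-9)

    def test_two_translations_add(self):
        a = RigidTransform(np.eye(3), [1, 0, 0])
        b = RigidTransform(np.eye(3), [0, 2, 0])
        assert np.allclose(compose(a, b).translation, [1, 2, 0])

    def test_rigidity_preserves_pairwise_distances(self, rng):
        pts = rng.normal(size=(50, 3)) * 100
        t = RigidTransform.from_axis_angle(rng.normal(size=3), 73.0, [10, -4, 2])
        moved = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-6)

    def test_apply_transform_preserves_topology(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        t = RigidTransform.from_axis_angle([0, 1, 0], 45.0, [1, 1, 1])
        out = apply_transform(t, mesh)
        assert np.array_equal(out.faces, mesh.faces)
        ps = apply_transform(t, PointSet([[0, 0, 0]]))
        assert isinstance(ps, PointSet)

    def test_json_round_trip(self, tmp_path):
        t = RigidTransform.from_axis_angle([3, 1, 2], 21.0, [7.0, 8.0, 9.0])
        t.to_json(tmp_path / "t.json")
        back = RigidTransform.from_json(tmp_path / "t.json")
        assert np.allclose(back.as_matrix(), t.as_matrix(), atol=1e-12)


class TestVolumeTypes:
    def test_world_coordinate_of_voxel(self):
        # voxel (k, j, i) -> origin + (i*sx, j*sy, k*sz)
        w = voxel_to_world(np.array([2, 3, 4]), spacing=(0.5, 2.0, 1.5), origin=(10, 20, 30))
        assert np.allclose(w, [10 + 4 * 0.5, 20 + 3 * 2.0, 30 + 2 * 1.5])

    def test_invalid_spacing_rejected(self):
        with pytest.raises(InvariantError):
            ScalarVolume(np.zeros((2, 2, 2)), spacing=(1.0, 0.0, 1.0))

    def test_mask_values_validated(self):
        with pytest.raises(InvariantError):
            BinaryVolume(np.full((2, 2, 2), 7))

    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(InvariantError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 3]])

    def test_degenerate_face_rejected(self):
        with pytest.raises(InvariantError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]])


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nii.gz", ".nii", ".nrrd"])
    def test_round_trip_identity(self, tmp_path, rng, suffix):
        data = rng.integers(0, 1000, size=(5, 6, 7)).astype(np.int16)
        vol = ScalarVolume(data, spacing=(0.7, 0.7, 2.5), origin=(1.0, -2.0, 3.0))
        path = tmp_path / f"vol{suffix}"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.array_equal(back.data, data)
        assert np.allclose(back.spacing, (0.7, 0.7, 2.5))
        assert np.allclose(back.origin, (1.0, -2.0, 3.0))

    def test_single_voxel_volume(self, tmp_path):
        write_volume(ScalarVolume(np.array([[[42.0]]])), tmp_path / "one.nii.gz")
        back = read_volume(tmp_path / "one.nii.gz")
        assert back.shape == (1, 1, 1)
        assert back.data[0, 0, 0] == 42.0

    def test_unknown_format_rejected(self, tmp_path):
        (tmp_path / "x.foo").write_text("junk")
        with pytest.raises(FormatError, match="format"):
            read_volume(tmp_path / "x.foo")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii.gz")


class TestMeshIO:
    TET_V = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
    TET_F = [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]

    @pytest.mark.parametrize("fmt", ["ply", "obj", "stl"])
    def test_tetrahedron_round_trip(self, tmp_path, fmt):
        mesh = TriangleMesh(self.TET_V, self.TET_F)
        path = tmp_path / f"tet.{fmt}"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert back.n_faces == 4
        # STL stores a triangle soup, so vertices may come back unmerged
        uniq = np.unique(np.round(back.vertices, 5), axis=0)
        assert len(uniq) == 4
        assert np.allclose(np.sort(uniq, axis=0),
                           np.sort(np.asarray(self.TET_V, float), axis=0), atol=1e-5)
        if fmt != "stl":
            assert back.n_vertices == 4

    def test_empty_mesh_ply_ok_stl_rejected(self, tmp_path):
        empty = TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
        write_mesh(empty, tmp_path / "e.ply")
        with pytest.raises(FormatError, match="STL"):
            write_mesh(empty, tmp_path / "e.stl")

    def test_unsupported_format_lists_alternatives(self, tmp_path):
        mesh = TriangleMesh(self.TET_V, self.TET_F)
        with pytest.raises(FormatError, match="ply, obj, stl"):
            write_mesh(mesh, tmp_path / "m.xyz")

    def test_point_cloud_round_trip(self, tmp_path, rng):
        ps = PointSet(rng.normal(size=(100, 3)) * 50)
        write_point_set(ps, tmp_path / "c.ply")
        back = read_point_set(tmp_path / "c.ply")
        assert np.allclose(np.sort(back.points, axis=0), np.sort(ps.points, axis=0), atol=1e-4)
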