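import numpy as np
import pytest

from atriflow import mesh_core as mc


class TestIO:
    @pytest.mark.parametrize("fmt", ["ply", "off", "stl", "vtk"])
    def test_round_trip_preserves_geometry(self, unit_cube, tmp_path, fmt):
        path = tmp_path / f"cube.{fmt}"
        mc.write_mesh(unit_cube, str(path))
        back = mc.read_mesh(str(path))
        assert back.n_faces == unit_cube.n_faces
        # connectivity-preserving formats keep arrays identical
        if fmt in ("ply", "off", "vtk"):
            np.testing.assert_allclose(back.vertices, unit_cube.vertices, atol=1e-12)
            np.testing.assert_array_equal(back.faces, unit_cube.faces)
        else:
            assert abs(mc.surface_area(back) - mc.surface_area(unit_cube)) < 1e-9

    def test_ply_face_labels_round_trip(self, unit_cube, tmp_path):
        mesh = unit_cube.copy()
        mesh.face_labels = np.arange(mesh.n_faces, dtype=np.int64) % 3
        path = tmp_path / "labeled.ply"
        mc.write_mesh(mesh, str(path))
        back = mc.read_mesh(str(path))
        np.testing.assert_array_equal(back.face_labels, mesh.face_labels)

    def test_unknown_extension_rejected(self, unit_cube, tmp_path):
        with pytest.raises(mc.MeshIOError, match="unsupported"):
            mc.write_mesh(unit_cube, str(tmp_path / "cube.obj"))

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text("ply\nformat ascii 1.0\nelement vertex 2\n"
                        "property double x\nproperty double y\nproperty double z\n"
                        "element face 0\nproperty list uchar int vertex_indices\n"
                        "end_header\n0 0 zero\n1 1 1\n")
        with pytest.raises(mc.MeshIOError, match="bad.ply:10"):
            mc.read_mesh(str(path))


class TestMeasures:
    def test_cube_area_and_volume(self, unit_cube):
        assert mc.surface_area(unit_cube) == pytest.approx(6.0)
        assert mc.enclosed_volume(unit_cube) == pytest.approx(1.0)

    def test_icosphere_volume_near_analytic(self, icosphere):
        # subdivision-3 icosphere volume converges to 4*pi/3 from below
        assert mc.enclosed_volume(icosphere) == pytest.approx(
            4.0 * np.pi / 3.0, rel=0.01)

    def test_open_mesh_volume_error_names_loops(self, straight_tube):
        mesh, _ = straight_tube
        with pytest.raises(ValueError, match="1 open boundary loop"):
            mc.enclosed_volume(mesh)

    def test_volume_translation_invariant(self, icosphere):
        v0 = mc.enclosed_volume(icosphere)
        shifted = mc.TriSurfaceMesh(icosphere.vertices + [11.0, -7.0, 3.0],
                                    icosphere.faces)
        assert abs(mc.enclosed_volume(shifted) - v0) < 1e-9 * v0

    def test_area_rigid_invariant(self, icosphere):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [0.3, -1.0, 2.2]).as_matrix()
        moved = mc.TriSurfaceMesh(icosphere.vertices @ R.T + 5.0, icosphere.faces)
        assert mc.surface_area(moved) == pytest.approx(
            mc.surface_area(icosphere), rel=1e-12)


class TestBoundaryLoops:
    def test_closed_surface_has_none(self, icosphere):
        assert mc.boundary_loops(icosphere) == []

    def test_open_cylinder_has_two(self):
        from atriflow.synthetic_anatomy import make_straight_vessel
        tube = make_straight_vessel(radius=0.5, length=2.0)
        assert len(mc.boundary_loops(tube)) == 2

    def test_laa_tube_has_one(self, straight_tube):
        mesh, _ = straight_tube
        assert len(mc.boundary_loops(mesh)) == 1

    def test_capping_all_ports_closes(self, template_la):
        capped = mc.cap_ports(template_la)
        assert mc.boundary_loops(capped) == []

    def test_non_manifold_edge_rejected(self):
        # three faces sharing one edge
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.0]])
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
        with pytest.raises(ValueError, match="non-manifold"):
            mc.boundary_loops(mc.TriSurfaceMesh(verts, faces))


class TestSmoothing:
    def test_zero_iterations_is_identity(self, icosphere):
        out = mc.laplacian_smooth(icosphere, iterations=0)
        np.testing.assert_array_equal(out.vertices, icosphere.vertices)

    def test_noisy_sphere_moves_toward_sphere(self):
        # fine sphere so denoising dominates the Laplacian shrinkage
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        icosphere = mc.TriSurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        rng = np.random.default_rng(0)
        noisy = mc.TriSurfaceMesh(
            icosphere.vertices * (1.0 + 0.01 * rng.standard_normal(
                (icosphere.n_vertices, 1))),
            icosphere.faces)
        sm = mc.laplacian_smooth(noisy, iterations=10, relaxation=0.5)
        def dev(m):
            return np.abs(np.linalg.norm(m.vertices, axis=1) - 1.0).max()
        assert dev(sm) < dev(noisy)

    def test_cube_shrinks(self, unit_cube):
        sm = mc.laplacian_smooth(unit_cube, iterations=5, relaxation=0.5)
        assert mc.enclosed_volume(sm) < mc.enclosed_volume(unit_cube)


class TestTetrahedralize:
    def test_cube_volume_conserved(self, cube_tet):
        assert cube_tet.tet_volumes().sum() == pytest.approx(1.0, abs=1e-6)

    def test_la_composite_has_all_patches(self, template_la):
        capped = mc.cap_ports(template_la)
        tet = mc.tetrahedralize(capped, 0.45)
        for name in ("PV1", "PV2", "PV3", "PV4", "MV", "OSTIUM", "WALL"):
            assert name in tet.label_names
            assert len(tet.patch_faces(name)) > 0
        # patch areas close to the analytic port discs
        assert tet.patch_area("MV") == pytest.approx(np.pi * 1.2**2, rel=0.1)
        assert tet.patch_area("PV1") == pytest.approx(np.pi * 0.55**2, rel=0.1)

    def test_open_surface_rejected(self, straight_tube):
        mesh, _ = straight_tube
        with pytest.raises(ValueError, match="watertight"):
            mc.tetrahedralize(mesh, 0.3)


def test_stitch_restores_composite(icosphere):
    half = icosphere.faces[icosphere.face_centroids()[:, 2] > 0]
    other = icosphere.faces[icosphere.face_centroids()[:, 2] <= 0]
    a = mc.TriSurfaceMesh(icosphere.vertices, half)
    b = mc.TriSurfaceMesh(icosphere.vertices, other)
    merged = mc.stitch(a, b)
    assert merged.n_faces == icosphere.n_faces
    assert mc.boundary_loops(merged) == []
    assert mc.enclosed_volume(merged) == pytest.approx(
        mc.enclosed_volume(icosphere))
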