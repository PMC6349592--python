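import numpy as np
import pytest
import trimesh

from atriflow import laa_grafting as lg
from atriflow import mesh_core as mc
from atriflow import sdf_segmentation as sdfm


class TestComputeSDF:
    def test_sphere_values_bounded_by_chords(self, small_sphere):
        # chords at cone angle theta have length 2r cos(theta)
        theta_max = np.pi / 3
        field = sdfm.compute_sdf(small_sphere, theta_max, n_rays=30, seed=1)
        assert np.all(field.values >= 2.0 * np.cos(theta_max) - 0.05)
        assert np.all(field.values <= 2.0 + 1e-6)
        cv = field.values.std() / field.values.mean()
        assert cv < 0.05

    def test_cylinder_lateral_wall_near_diameter(self):
        tube = trimesh.creation.cylinder(radius=0.5, height=6.0, sections=32)
        mesh = mc.TriSurfaceMesh(np.asarray(tube.vertices), np.asarray(tube.faces))
        field = sdfm.compute_sdf(mesh, np.pi / 3, n_rays=30, seed=1)
        lateral = np.abs(mesh.face_centroids()[:, 2]) < 2.0
        assert np.abs(field.values[lateral] - 1.0).max() < 0.1

    def test_degenerate_cone_single_ray(self, small_sphere):
        field = sdfm.compute_sdf(small_sphere, 0.0, n_rays=1, seed=1)
        # single antipodal ray: close to the diameter on a faceted sphere
        assert np.abs(field.values - 2.0).max() < 0.05

    def test_pose_invariance(self, small_sphere):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [0.4, 1.2, -0.7]).as_matrix()
        moved = mc.TriSurfaceMesh(
            small_sphere.vertices @ R.T + np.array([3.0, -2.0, 1.0]),
            small_sphere.faces)
        f0 = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=5)
        f1 = sdfm.compute_sdf(moved, np.pi / 3, 30, seed=5)
        assert np.abs(f1.values - f0.values).max() < 1e-6 * f0.values.mean()

    def test_scaling_linearity(self, small_sphere):
        scaled = mc.TriSurfaceMesh(small_sphere.vertices * 2.5, small_sphere.faces)
        f0 = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=5)
        f1 = sdfm.compute_sdf(scaled, np.pi / 3, 30, seed=5)
        np.testing.assert_allclose(f1.values, 2.5 * f0.values, rtol=1e-9)

    def test_oracle_equivalence_with_independent_ray_caster(self, small_sphere):
        """Dense SDF agrees with an independently implemented brute-force
        ray-casting oracle on a face subset."""
        subset = np.arange(0, small_sphere.n_faces, 5)
        field = sdfm.compute_sdf(small_sphere, np.pi / 3, n_rays=200, seed=2)
        oracle = _sdf_oracle(small_sphere, np.pi / 3, n_rays=200, seed=2,
                             face_subset=subset)
        rel = np.abs(field.values[subset] - oracle) / oracle
        assert np.median(rel) < 0.05


def _sdf_oracle(mesh: mc.TriSurfaceMesh, cone: float, n_rays: int, seed: int,
                face_subset: np.ndarray | None = None):
    """Brute-force SDF oracle, independent of the package's ray caster:
    ray/plane intersection followed by trimesh's barycentric inside test."""
    from trimesh.triangles import points_to_barycentric

    triangles = mesh.vertices[mesh.faces]
    tri_n = np.cross(triangles[:, 1] - triangles[:, 0],
                     triangles[:, 2] - triangles[:, 0])
    normals = mesh.face_normals()
    centroids = mesh.face_centroids()
    rng = np.random.default_rng(seed)
    faces = np.arange(mesh.n_faces) if face_subset is None else np.asarray(face_subset)
    out = np.empty(len(faces))
    n_tris = len(triangles)
    for oi, i in enumerate(faces):
        n = normals[i]
        a = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
        t1 = np.cross(n, a); t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        u = rng.random(n_rays)
        cos_t = 1.0 - u * (1.0 - np.cos(cone))
        sin_t = np.sqrt(1.0 - cos_t**2)
        phi = rng.random(n_rays) * 2 * np.pi
        dirs = (sin_t * np.cos(phi))[:, None] * t1 + (sin_t * np.sin(phi))[:, None] * t2 \
            - cos_t[:, None] * n
        origin = centroids[i] - 1e-6 * n
        angles = np.arccos(np.clip(cos_t, -1, 1))

        denom = dirs @ tri_n.T                                  # (R, T)
        num = np.einsum("tk,tk->t", triangles[:, 0] - origin, tri_n)
        t_plane = num[None, :] / np.where(np.abs(denom) > 1e-14, denom, np.inf)
        t_plane = np.where(t_plane > 1e-9, t_plane, np.inf)
        hits = origin + t_plane[:, :, None] * dirs[:, None, :]  # (R, T, 3)
        bary = points_to_barycentric(
            np.broadcast_to(triangles, (n_rays, n_tris, 3, 3)).reshape(-1, 3, 3),
            hits.reshape(-1, 3)).reshape(n_rays, n_tris, 3)
        inside = np.all(bary >= -1e-8, axis=2) & np.isfinite(t_plane)
        inside[:, i] = False
        t_hit = np.where(inside, t_plane, np.inf)
        nearest = np.argmin(t_hit, axis=1)
        t_near = t_hit[np.arange(n_rays), nearest]
        ok = np.isfinite(t_near)
        ok &= np.einsum("rk,k->r", normals[nearest], n) <= 0
        lengths = t_near[ok]
        kept_angles = angles[ok]
        med = np.median(lengths)
        keep = np.abs(lengths - med) <= lengths.std()
        w = 1.0 / np.maximum(kept_angles[keep], 1e-3)
        out[oi] = np.sum(w * lengths[keep]) / np.sum(w)
    return out


class TestClustering:
    def test_uniform_sphere_one_dominant_region(self, small_sphere):
        field = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=1)
        labels = sdfm.cluster_regions(field, small_sphere, k_clusters=2, seed=0)
        frac = np.bincount(labels.labels).max() / len(labels.labels)
        assert frac >= 0.95

    def test_two_bodies_different_labels(self):
        """Spheres of radius 1 and 2 joined by a thin neck separate."""
        s1 = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        s1.apply_translation([0, 0, 2.8])
        s2 = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        neck = trimesh.creation.cylinder(radius=0.3, height=1.2, sections=16)
        neck.apply_translation([0, 0, 1.6])
        blob = trimesh.util.concatenate([s2, neck, s1])
        blob.merge_vertices()
        blob.process(validate=True)
        mesh = mc.TriSurfaceMesh(np.asarray(blob.vertices), np.asarray(blob.faces))
        field = sdfm.compute_sdf(mesh, np.pi / 3, 30, seed=1)
        labels = sdfm.cluster_regions(field, mesh, k_clusters=3, seed=0)
        c1 = mesh.face_centroids()[:, 2] > 2.8
        c2 = mesh.face_centroids()[:, 2] < 0.0
        lab1 = np.bincount(labels.labels[c1]).argmax()
        lab2 = np.bincount(labels.labels[c2]).argmax()
        assert lab1 != lab2

    def test_single_cluster_single_region(self, small_sphere):
        field = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=1)
        labels = sdfm.cluster_regions(field, small_sphere, k_clusters=1,
                                      spatial_weight=0.0, seed=0)
        assert len(np.unique(labels.labels)) == 1

    def test_chamber_is_modal_label(self, small_sphere):
        field = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=1)
        labels = sdfm.cluster_regions(field, small_sphere, k_clusters=2, seed=0)
        assert labels.chamber_id == np.bincount(labels.labels).argmax()

    def test_too_many_clusters_rejected(self, small_sphere):
        field = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=1)
        field.values[:] = 1.0
        with pytest.raises(ValueError, match="distinct"):
            sdfm.cluster_regions(field, small_sphere, k_clusters=4, seed=0)


@pytest.fixture(scope="module")
def composite_with_truth(study_set2):
    """Composite model plus the known appendage face set."""
    template, variants = study_set2
    laa = variants[1][0]
    T, _ = lg.align_donor(laa, template)
    composite = lg.graft(template, laa, T, smooth_iterations=0)
    capped = mc.cap_ports(composite, ports=list(composite.port_loops))
    # faces belonging to the donor body occupy a contiguous index range
    n_template = template.n_faces
    n_laa = laa.n_faces
    truth = np.arange(n_template, n_template + n_laa)
    return capped, composite, truth, n_template, n_laa


class TestIdentifyLAA:
    def test_recovers_known_appendage_faces(self, composite_with_truth):
        """Automatic isolation (no hint) overlaps >= 90% with the faces the
        generator grafted on."""
        capped, composite, truth, n_template, n_laa = composite_with_truth
        field = sdfm.compute_sdf(capped, seed=3)
        labels = sdfm.cluster_regions(field, capped, k_clusters=4, seed=0)
        got = sdfm.identify_laa(labels, capped)
        inter = len(set(got.tolist()) & set(truth.tolist()))
        assert inter / n_laa >= 0.9

    def test_hint_on_chamber_errors(self, composite_with_truth):
        capped, composite, truth, *_ = composite_with_truth
        field = sdfm.compute_sdf(capped, seed=3)
        labels = sdfm.cluster_regions(field, capped, k_clusters=4, seed=0)
        chamber_face = np.flatnonzero(labels.labels == labels.chamber_id)[0]
        hint = capped.face_centroids()[chamber_face]
        with pytest.raises(ValueError, match="chamber"):
            sdfm.identify_laa(labels, capped, hint=hint)

    def test_no_candidate_errors(self, small_sphere):
        field = sdfm.compute_sdf(small_sphere, np.pi / 3, 30, seed=1)
        labels = sdfm.cluster_regions(field, small_sphere, k_clusters=2, seed=0)
        with pytest.raises(ValueError, match="no appendage candidate"):
            sdfm.identify_laa(labels, small_sphere)


class TestExtractSubmesh:
    def test_known_face_set_single_loop(self, composite_with_truth):
        capped, composite, truth, *_ = composite_with_truth
        sub, rem = sdfm.extract_submesh(composite, truth)
        assert len(mc.boundary_loops(sub)) == 1
        assert "OSTIUM" in sub.port_loops and "OSTIUM" in rem.port_loops

    def test_disconnected_face_set_rejected(self, composite_with_truth):
        _, composite, truth, *_ = composite_with_truth
        bad = np.concatenate([truth[:10], np.array([0, 1, 2])])
        with pytest.raises(ValueError, match="edge-connected"):
            sdfm.extract_submesh(composite, bad)

    def test_extract_then_stitch_identity(self, composite_with_truth):
        _, composite, truth, *_ = composite_with_truth
        sub, rem = sdfm.extract_submesh(composite, truth)
        merged = mc.stitch(rem, sub)
        assert merged.n_faces == composite.n_faces
        assert mc.surface_area(merged) == pytest.approx(
            mc.surface_area(composite), rel=1e-12)
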