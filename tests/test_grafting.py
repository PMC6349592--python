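import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from atriflow import laa_grafting as lg
from atriflow import mesh_core as mc
from atriflow import sdf_segmentation as sdfm


@pytest.fixture()
def cloud():
    return np.random.default_rng(3).normal(size=(200, 3))


class TestICP:
    def test_identical_sets_identity(self, cloud):
        T, rms = lg.icp_align(cloud, cloud)
        assert rms < 1e-12
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_recovery(self, cloud, seed):
        R = Rotation.random(random_state=seed).as_matrix()
        t = np.random.default_rng(seed).normal(size=3) * 2.0
        moved = cloud @ R.T + t
        T, rms = lg.icp_align(cloud, moved)
        assert rms < 1e-9
        np.testing.assert_allclose(T.rotation, R, atol=1e-6)
        np.testing.assert_allclose(T.translation, t, atol=1e-6)

    def test_scale_recovery(self, cloud):
        R = Rotation.random(random_state=1).as_matrix()
        t = np.array([0.3, -1.2, 2.0])
        moved = 1.5 * (cloud @ R.T) + t
        T, rms = lg.icp_align(cloud, moved, with_scale=True)
        assert T.scale == pytest.approx(1.5, abs=1e-6)
        assert rms < 1e-9

    def test_collinear_sets_rejected(self):
        line = np.outer(np.linspace(0, 1, 50), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            lg.icp_align(line, line + 1.0)

    def test_rms_non_increasing(self, cloud):
        rng = np.random.default_rng(7)
        noisy = cloud @ Rotation.random(random_state=7).as_matrix().T \
            + rng.normal(size=(200, 3)) * 0.05 + 1.0
        _, _, history = lg.icp_align(cloud, noisy, return_history=True)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))


class TestGraft:
    def test_composite_has_only_pv_mv_ports(self, study_set2):
        template, variants = study_set2
        T, _ = lg.align_donor(variants[0][0], template)
        composite = lg.graft(template, variants[0][0], T)
        loops = mc.boundary_loops(composite)
        assert len(loops) == 5  # PV1-4 + MV
        assert set(composite.port_loops) == {"PV1", "PV2", "PV3", "PV4", "MV"}

    def test_watertight_after_capping(self, study_set2):
        template, variants = study_set2
        T, _ = lg.align_donor(variants[1][0], template)
        composite = lg.graft(template, variants[1][0], T)
        capped = mc.cap_ports(composite, ports=list(composite.port_loops))
        assert mc.boundary_loops(capped) == []

    def test_volume_additivity(self, study_set2):
        """Composite volume = template volume + donor volume within the
        seam-band tolerance."""
        template, variants = study_set2
        v_template = mc.enclosed_volume(mc.cap_ports(template))
        for laa, gt, _ in variants:
            T, _ = lg.align_donor(laa, template)
            composite = lg.graft(template, laa, T)
            v = mc.enclosed_volume(mc.cap_ports(composite, ports=list(composite.port_loops)))
            assert v - v_template == pytest.approx(gt.volume, rel=0.08)

    def test_cut_and_restore_round_trip(self, study_set2):
        """Grafting back the appendage cut from a composite restores the
        enclosed volume within 1%."""
        template, variants = study_set2
        T, _ = lg.align_donor(variants[0][0], template)
        composite = lg.graft(template, variants[0][0], T, smooth_iterations=0)
        v_ref = mc.enclosed_volume(mc.cap_ports(composite, ports=list(composite.port_loops)))
        n_template = template.n_faces
        truth = np.arange(n_template, n_template + variants[0][0].n_faces)
        laa_cut, remainder = sdfm.extract_submesh(composite, truth)
        restored = lg.graft(remainder, laa_cut, lg.RigidTransform.identity(),
                            smooth_iterations=0)
        v_new = mc.enclosed_volume(mc.cap_ports(restored, ports=list(restored.port_loops)))
        assert v_new == pytest.approx(v_ref, rel=0.01)

    def test_forced_flip_raises(self, study_set2):
        template, variants = study_set2
        T, _ = lg.align_donor(variants[0][0], template)
        with pytest.raises(ValueError, match="seam"):
            lg.graft(template, variants[0][0], T, orientation="flip")

    def test_perimeter_mismatch_warns(self, study_set2):
        template, variants = study_set2
        laa = variants[0][0]
        shrunk = mc.TriSurfaceMesh(
            laa.vertices * 0.25, laa.faces.copy(),
            port_loops={k: v.copy() for k, v in laa.port_loops.items()})
        T, _ = lg.align_donor(shrunk, template)
        with pytest.warns(UserWarning, match="perimeter"):
            lg.graft(template, shrunk, T)


class TestBuildModelSet:
    def test_chamber_vertices_shared_bitwise(self, study_set2):
        template, variants = study_set2
        models = lg.build_model_set(template, [v[0] for v in variants])
        assert len(models) == 2
        n = template.n_vertices
        a = models[0].vertices[:n]
        b = models[1].vertices[:n]
        same = np.all(a == b, axis=1)
        assert same.mean() > 0.9  # identical outside the seam band

    def test_empty_donor_list(self, study_set2):
        template, _ = study_set2
        assert lg.build_model_set(template, []) == []

    def test_runtime_under_a_minute_per_model(self, study_set2):
        import time
        template, variants = study_set2
        t0 = time.time()
        lg.build_model_set(template, [variants[0][0]])
        assert time.time() - t0 < 60.0
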