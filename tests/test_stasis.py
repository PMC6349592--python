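import numpy as np
import pytest

from atriflow import hemodynamics as hd
from atriflow import laa_geometry as geo
from atriflow import mesh_core as mc
from atriflow import stasis_postprocess as st
from atriflow import synthetic_anatomy as sa


@pytest.fixture(scope="module")
def box_tet():
    import trimesh
    box = trimesh.creation.box(extents=(2, 2, 2))
    cube = mc.TriSurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
    return mc.tetrahedralize(cube, 0.3)


def _series(tet, u, n_steps=40, dt=0.005):
    times = np.arange(n_steps + 1) * dt
    return hd.FlowFieldSeries(
        mesh=tet, times=times,
        velocities=np.repeat(u[None].astype(np.float32), len(times), axis=0),
        pressures=np.zeros((len(times), tet.n_vertices), dtype=np.float32),
        patch_flux={}, dvdt=np.zeros(len(times)),
        mass_defect=np.zeros(len(times)),
        displacement_mode=np.zeros((tet.n_vertices, 3)), motion=None,
        config=hd.SolverConfig(dt=dt, n_cycles=1))


class TestQCriterion:
    def test_uniform_flow_zero(self, box_tet):
        u = np.tile([3.0, -1.0, 2.0], (box_tet.n_vertices, 1))
        q = st.q_criterion(box_tet, u)
        assert np.abs(q.values).max() < 1e-9

    def test_solid_rotation(self, box_tet):
        omega = 3.0
        v = box_tet.vertices
        u = np.column_stack([-omega * v[:, 1], omega * v[:, 0], np.zeros(len(v))])
        q = st.q_criterion(box_tet, u, "printed")
        np.testing.assert_allclose(q.values, 4 * omega**2, rtol=1e-8)

    def test_pure_strain(self, box_tet):
        alpha = 2.0
        v = box_tet.vertices
        u = np.column_stack([alpha * v[:, 0], -alpha * v[:, 1], np.zeros(len(v))])
        q = st.q_criterion(box_tet, u, "printed")
        np.testing.assert_allclose(q.values, -4 * alpha**2, rtol=1e-8)

    def test_simple_shear_zero(self, box_tet):
        gamma = 1.5
        v = box_tet.vertices
        u = np.column_stack([gamma * v[:, 1], np.zeros(len(v)), np.zeros(len(v))])
        q = st.q_criterion(box_tet, u, "printed")
        assert np.abs(q.values).max() < 1e-9

    def test_convention_factor_four(self, box_tet):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((box_tet.n_vertices, 3))
        qp = st.q_criterion(box_tet, u, "printed")
        qs = st.q_criterion(box_tet, u, "standard")
        np.testing.assert_allclose(qp.values, 4.0 * qs.values, rtol=1e-12)

    def test_galilean_invariance(self, box_tet):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((box_tet.n_vertices, 3))
        q0 = st.q_criterion(box_tet, u)
        q1 = st.q_criterion(box_tet, u + np.array([7.0, -4.0, 2.0]))
        assert np.abs(q1.values - q0.values).max() < 1e-10 * max(
            1.0, np.abs(q0.values).max())


class TestVortexRegions:
    def test_all_positive_one_region(self, box_tet):
        q = st.QCriterionField(np.ones(box_tet.n_tets), "printed")
        regions = st.vortex_regions(q, box_tet)
        assert len(regions) == 1
        assert len(regions[0]["cells"]) == box_tet.n_tets

    def test_all_negative_empty(self, box_tet):
        q = st.QCriterionField(-np.ones(box_tet.n_tets), "printed")
        assert st.vortex_regions(q, box_tet) == []

    def test_two_embedded_vortices(self, box_tet):
        """Two rotating patches in a strain background give two regions."""
        v = box_tet.vertices
        c1, c2 = np.array([-0.5, 0, 0]), np.array([0.5, 0, 0])
        u = np.column_stack([0.1 * v[:, 0], -0.1 * v[:, 1], np.zeros(len(v))])
        for c in (c1, c2):
            d = v - c
            r2 = (d[:, :2]**2).sum(axis=1)
            w = 5.0 * np.exp(-r2 / 0.04)
            u[:, 0] += -w * d[:, 1]
            u[:, 1] += w * d[:, 0]
        q = st.q_criterion(box_tet, u)
        regions = st.vortex_regions(q, box_tet, u)
        assert len(regions) >= 2
        centers = [box_tet.vertices[box_tet.tets[r["cells"]]].mean(axis=(0, 1))
                   for r in regions[:2]]
        xs = sorted(c[0] for c in centers)
        assert xs[0] < 0 < xs[1]


class TestOstiumTrace:
    def test_orientation_convention(self, box_tet):
        """Uniform flow along the section normal reads positive (emptying)."""
        th = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        rim = np.column_stack([0.5 * np.cos(th), 0.5 * np.sin(th), np.zeros(32)])
        section = st.ostium_section(rim, chamber_side_point=np.array([0, 0, 1.0]))
        u = np.tile([0.0, 0.0, 10.0], (box_tet.n_vertices, 1))
        series = _series(box_tet, u, n_steps=4)
        trace = st.ostium_velocity(series, section)
        np.testing.assert_allclose(trace.velocity, 10.0, rtol=1e-6)
        u_rev = -u
        trace_rev = st.ostium_velocity(_series(box_tet, u_rev, 4), section)
        np.testing.assert_allclose(trace_rev.velocity, -10.0, rtol=1e-6)

    def test_zero_field_flags_low_washout(self, box_tet):
        th = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        rim = np.column_stack([0.5 * np.cos(th), 0.5 * np.sin(th), np.zeros(32)])
        section = st.ostium_section(rim, np.array([0, 0, 1.0]))
        series = _series(box_tet, np.zeros((box_tet.n_vertices, 3)), 4)
        trace = st.ostium_velocity(series, section)
        assert np.all(trace.velocity == 0.0)
        assert trace.low_washout

    def test_section_outside_mesh_rejected(self, box_tet):
        th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        rim = np.column_stack([np.cos(th), np.sin(th), np.full(16, 50.0)])
        section = st.ostium_section(rim, np.array([0, 0, 60.0]))
        series = _series(box_tet, np.zeros((box_tet.n_vertices, 3)), 2)
        with pytest.raises(ValueError, match="outside"):
            st.ostium_velocity(series, section)


class TestSeeding:
    @pytest.fixture(scope="class")
    def laa_setup(self, straight_tube):
        mesh, _ = straight_tube
        closed = mc.cap_ports(mesh)
        center = geo.compute_centerline(mesh)
        return closed, center

    def test_all_inside(self, laa_setup):
        closed, center = laa_setup
        pts = st.seed_particles(closed, center, n=500, seed=3)
        assert len(pts) == 500
        assert closed.contains(pts).all()

    def test_same_seed_identical(self, laa_setup):
        closed, center = laa_setup
        p1 = st.seed_particles(closed, center, n=50, seed=9)
        p2 = st.seed_particles(closed, center, n=50, seed=9)
        np.testing.assert_array_equal(p1, p2)

    def test_sphere_centered_at_midpoint(self, laa_setup):
        closed, center = laa_setup
        pts = st.seed_particles(closed, center, n=2000, seed=1)
        seg = np.linalg.norm(np.diff(center.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        mid = np.array([np.interp(0.5 * s[-1], s, center.points[:, k])
                        for k in range(3)])
        np.testing.assert_allclose(pts.mean(axis=0), mid, atol=0.05)

    def test_degenerate_lumen_rejected(self, laa_setup):
        closed, center = laa_setup
        tiny = mc.TriSurfaceMesh(closed.vertices * 1e-4, closed.faces)
        small_center = geo.Centerline(center.points * 1e-4,
                                      center.L * 1e-4, center.D * 1e-4)
        with pytest.raises(ValueError, match="degenerate"):
            st.seed_particles(tiny, small_center, n=10, seed=0)


class TestAdvect:
    def test_zero_field_static(self, box_tet):
        series = _series(box_tet, np.zeros((box_tet.n_vertices, 3)), 10)
        p0 = np.array([[0.2, 0.1, -0.3], [0.0, 0.0, 0.0]])
        ens = st.advect(series, p0, outlet_patch="WALL")
        np.testing.assert_array_equal(ens.positions[-1], p0)

    def test_uniform_field_exact_displacement(self, box_tet):
        u = np.tile([1.0, 0, 0], (box_tet.n_vertices, 1))
        series = _series(box_tet, u, n_steps=100, dt=0.005)  # 0.5 s
        p0 = np.array([[-0.8, 0.2, 0.1]])
        ens = st.advect(series, p0, outlet_patch="WALL")
        np.testing.assert_allclose(
            ens.positions[-1][0], p0[0] + [0.5, 0, 0], atol=1e-6)

    def test_rigid_rotation_closed_orbit(self, box_tet):
        omega = 2 * np.pi
        v = box_tet.vertices
        u = np.column_stack([-omega * v[:, 1], omega * v[:, 0], np.zeros(len(v))])
        series = _series(box_tet, u, n_steps=200, dt=0.005)  # one period
        p0 = np.array([[0.5, 0.0, 0.1]])
        ens = st.advect(series, p0, outlet_patch="WALL")
        assert np.linalg.norm(ens.positions[-1] - p0) < 1e-3


class TestResidence:
    def test_static_particles_counted_every_cycle(self, box_tet, straight_tube):
        mesh, _ = straight_tube
        closed = mc.cap_ports(mesh)
        center = geo.compute_centerline(mesh)
        p0 = st.seed_particles(closed, center, n=40, seed=0)
        ens = st.ParticleEnsemble(
            initial=p0, positions=np.repeat(p0[None], 4, axis=0),
            times=np.array([0.0, 0.8, 1.6, 2.4]),
            departed=np.zeros(40, dtype=bool))
        counts = st.residence_counts(ens, closed, [0.8, 1.6, 2.4])
        assert all(c == 40 for c in counts.values())

    def test_half_expelled(self, straight_tube):
        mesh, _ = straight_tube
        closed = mc.cap_ports(mesh)
        center = geo.compute_centerline(mesh)
        p0 = st.seed_particles(closed, center, n=40, seed=0)
        moved = p0.copy()
        moved[:20] += np.array([50.0, 0, 0])  # push half far outside
        ens = st.ParticleEnsemble(
            initial=p0, positions=np.stack([p0, moved]),
            times=np.array([0.0, 0.8]), departed=np.zeros(40, dtype=bool))
        counts = st.residence_counts(ens, closed, [0.8])
        assert counts[0.8] == 20

    def test_relabeling_invariance(self, straight_tube):
        mesh, _ = straight_tube
        closed = mc.cap_ports(mesh)
        center = geo.compute_centerline(mesh)
        p0 = st.seed_particles(closed, center, n=30, seed=0)
        perm = np.random.default_rng(0).permutation(30)
        for order in (np.arange(30), perm):
            ens = st.ParticleEnsemble(
                initial=p0[order], positions=p0[order][None],
                times=np.array([0.0]), departed=np.zeros(30, dtype=bool))
            counts = st.residence_counts(ens, closed, [0.0])
            assert st.residual_fraction(counts[0.0], 30) == 100.0


class TestResidualFraction:
    @pytest.mark.parametrize("count,expected", [
        (168, 33.6), (58, 11.6), (103, 20.6), (312, 62.4), (126, 25.2),
        (500, 100.0), (0, 0.0),
    ])
    def test_percentages(self, count, expected):
        assert st.residual_fraction(count, 500) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.residual_fraction(1, 0)
        with pytest.raises(ValueError):
            st.residual_fraction(501, 500)
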