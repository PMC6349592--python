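import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriflow import hemodynamics as hd
from atriflow import mesh_core as mc
from atriflow import synthetic_anatomy as sa


class TestWaveform:
    def test_systole_is_zero(self):
        w = hd.MVWaveform()
        ts = np.linspace(0, w.systole_frac * w.period - 1e-6, 50)
        assert np.all(hd.mv_flowrate(ts, w) == 0.0)

    def test_peak_at_e_wave_midpoint(self):
        w = hd.MVWaveform()
        t_mid = (w.systole_frac + 0.5 * w.e_frac) * w.period
        assert hd.mv_flowrate(t_mid, w) == pytest.approx(w.q_peak)

    def test_stroke_volume_integral(self):
        w = hd.MVWaveform()
        ts = np.linspace(0, w.period, 20001)
        integral = np.trapezoid(hd.mv_flowrate(ts, w), ts)
        assert integral == pytest.approx(w.stroke_volume, rel=1e-5)
        assert integral == pytest.approx(
            w.q_peak * (2 / np.pi) * w.e_frac * w.period, rel=1e-5)

    def test_periodicity_and_nonnegativity(self):
        w = hd.MVWaveform()
        ts = np.linspace(0, 3 * w.period, 700)
        q = hd.mv_flowrate(ts, w)
        assert np.all(q >= 0.0)
        np.testing.assert_allclose(q[:200], hd.mv_flowrate(ts[:200] + w.period, w))


class TestWallMotion:
    def test_zero_at_t0(self):
        spec = hd.WallMotionSpec(seed=4)
        verts = np.random.default_rng(0).normal(size=(50, 3))
        d = hd.wall_displacement(0.0, verts, spec, normals=verts)
        np.testing.assert_allclose(d, 0.0)

    def test_amplitude_bound(self):
        spec = hd.WallMotionSpec(seed=4)
        verts = np.random.default_rng(0).normal(size=(200, 3))
        normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        worst = 0.0
        for t in np.linspace(0, 1.0, 37):
            d = hd.wall_displacement(t, verts, spec, normals=normals)
            worst = max(worst, np.linalg.norm(d, axis=1).max())
        assert worst <= 0.01 + 1e-12  # 0.1 mm

    def test_same_seed_identical(self):
        spec = hd.WallMotionSpec(seed=11)
        verts = np.random.default_rng(0).normal(size=(80, 3))
        d1 = hd.wall_displacement(0.123, verts, spec, normals=verts)
        d2 = hd.wall_displacement(0.123, verts, spec, normals=verts)
        np.testing.assert_array_equal(d1, d2)


class TestFlowSplit:
    def test_equal_areas_pure_outflow(self):
        q = hd.pv_flow_split(100.0, 0.0, np.ones(4))
        np.testing.assert_allclose(q, -25.0)

    def test_shrinking_volume(self):
        q = hd.pv_flow_split(0.0, -40.0, np.ones(4))
        np.testing.assert_allclose(q, 10.0)

    def test_area_proportionality(self):
        q = hd.pv_flow_split(100.0, 0.0, np.array([1.0, 2, 3, 4]))
        np.testing.assert_allclose(q, [-10.0, -20.0, -30.0, -40.0])

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            hd.pv_flow_split(1.0, 0.0, np.zeros(4))

    @settings(max_examples=200, deadline=None)
    @given(
        q_mv=st.floats(-500, 500),
        dvdt=st.floats(-200, 200),
        areas=st.tuples(*[st.floats(0.1, 5.0)] * 4),
        q_wall=st.tuples(*[st.floats(-30, 30)] * 4),
    )
    def test_mass_balance_exact(self, q_mv, dvdt, areas, q_wall):
        """Absolute section fluxes close the cavity mass balance to
        machine precision."""
        q = hd.pv_flow_split(q_mv, dvdt, np.array(areas), np.array(q_wall))
        residual = (q + np.array(q_wall)).sum() + q_mv + dvdt
        assert abs(residual) < 1e-10


@pytest.fixture(scope="module")
def small_channel_tet():
    tube = sa.make_straight_vessel(radius=0.5, length=3.0, n_theta=24,
                                   axial_spacing=0.25)
    capped = mc.cap_ports(tube)
    return mc.tetrahedralize(capped, 0.22)


class TestSolver:
    def test_rest_stays_at_rest(self, small_channel_tet):
        solver = hd.ProjectionSolver(
            small_channel_tet, config=hd.SolverConfig(dt=0.01, n_cycles=1))
        series = solver.run(0.1, inlet_flux={"PV1": lambda t: 0.0})
        assert np.abs(series.velocities).max() < 1e-10

    def test_determinism_bitwise(self, small_channel_tet):
        cfg = hd.SolverConfig(dt=0.01, n_cycles=1)
        runs = []
        for _ in range(2):
            solver = hd.ProjectionSolver(small_channel_tet, config=cfg)
            s = solver.run(0.05, inlet_flux={"PV1": lambda t: -0.5},
                           motion=hd.WallMotionSpec(seed=3))
            runs.append(s.velocities)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_backflow_penalization_dissipates_energy(self, small_channel_tet):
        """Unforced flow with beta > 0: discrete kinetic energy decays."""
        solver = hd.ProjectionSolver(
            small_channel_tet, config=hd.SolverConfig(dt=0.01, n_cycles=1, beta=0.2))
        rng = np.random.default_rng(0)
        u0 = 1e-2 * rng.standard_normal((small_channel_tet.n_vertices, 3))
        u0[solver.dirichlet_nodes] = 0.0
        series = solver.run(0.15, inlet_flux={"PV1": lambda t: 0.0}, u0=u0)
        ml = solver.ops.mass_lumped
        ke = [float((ml[:, None] * v.astype(float)**2).sum()) for v in series.velocities]
        assert all(b <= a + 1e-14 for a, b in zip(ke, ke[1:]))

    def test_temporal_refinement_consistency(self, small_channel_tet):
        """Halving dt changes the steady centerline velocity by < 10%."""
        out = {}
        for dt in (0.02, 0.01):
            solver = hd.ProjectionSolver(
                small_channel_tet, config=hd.SolverConfig(dt=dt, n_cycles=1))
            s = solver.run(1.2, inlet_flux={"PV1": lambda t: -np.pi * 0.25},
                           record_from=1.1)
            out[dt] = s.velocities[-1].astype(float)
        diff = np.linalg.norm(out[0.02] - out[0.01])
        ref = np.linalg.norm(out[0.01])
        assert diff / ref < 0.10

    def test_divergence_aborts_with_step_diagnostic(self, small_channel_tet):
        solver = hd.ProjectionSolver(
            small_channel_tet, config=hd.SolverConfig(dt=0.01, n_cycles=1))
        bad = np.full((small_channel_tet.n_vertices, 3), np.nan)
        with pytest.raises(FloatingPointError, match="step 1"):
            solver.run(0.05, inlet_flux={"PV1": lambda t: 0.0}, u0=bad)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": -1.0}, {"n_cycles": 0}, {"beta": 2.0}, {"inlet_profile": "spiral"},
    ])
    def test_bad_solver_configs(self, kwargs):
        with pytest.raises(ValueError):
            hd.SolverConfig(**kwargs)

    def test_bad_waveform(self):
        with pytest.raises(ValueError):
            hd.MVWaveform(systole_frac=0.9, e_frac=0.5)
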