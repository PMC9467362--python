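"""Larval dynamics: equations of motion, Jeffery rotation, settlement rules,
the seeding lattice and the vectorized simulation."""

import numpy as np
import pytest

from larvaflow import flowfield as ff, larvasim as lv
from conftest import rotation_flow, shear_flow, uniform_flow


class TestShapeParameter:
    def test_values(self):
        assert lv.shape_parameter(1.0, 1.0) == 0.0
        assert lv.shape_parameter(1.0, 1e-8) == pytest.approx(1.0, abs=1e-10)
        assert lv.shape_parameter(0.25, 0.15) == pytest.approx(0.470588, abs=1e-6)

    def test_invalid(self):
        with pytest.raises(ValueError):
            lv.shape_parameter(0.1, 0.2)


class TestEquationsOfMotion:
    @pytest.mark.parametrize("U,theta,expected", [
        ((10.0, 0.0), np.pi / 2, (10.0, 3.0)),
        ((0.0, 0.0), 0.0, (3.0, 0.0)),
        ((-4.0, 1.0), np.pi, (-7.0, 1.0)),
    ])
    def test_larval_velocity(self, U, theta, expected):
        st = lv.LarvaState(x=0, y=0, theta=theta)
        np.testing.assert_allclose(lv.larval_velocity(st, U), expected,
                                   atol=1e-12)

    def test_rotation_uniform_flow_zero(self):
        st = lv.LarvaState(x=0, y=0, theta=0.7)
        assert lv.larval_rotation(st, 0.0, np.zeros((2, 2))) == 0.0

    def test_rotation_sphere_in_shear(self):
        # u = gamma y, gamma = 1: omega_z = -1, S_xy = 1/2
        S = np.array([[0.0, 0.5], [0.5, 0.0]])
        sphere = lv.LarvaParams(a=0.2, b=0.2)
        for th in np.linspace(0, 2 * np.pi, 9):
            st = lv.LarvaState(x=0, y=0, theta=th)
            assert lv.larval_rotation(st, -1.0, S, sphere) == pytest.approx(-0.5)

    def test_rotation_ellipsoid_in_shear(self):
        S = np.array([[0.0, 0.5], [0.5, 0.0]])
        st = lv.LarvaState(x=0, y=0, theta=0.0)
        assert lv.larval_rotation(st, -1.0, S) == pytest.approx(-0.264706, abs=1e-6)

    def test_nonsymmetric_tensor_rejected(self):
        st = lv.LarvaState(x=0, y=0, theta=0.0)
        with pytest.raises(ValueError):
            lv.larval_rotation(st, 0.0, np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestStep:
    def test_zero_field_passive_unchanged(self):
        prov = uniform_flow(0.0, 0.0)
        st = lv.LarvaState(x=5.0, y=5.0, theta=1.0)
        out = lv.step(st, prov, lv.LarvaParams(u_ell=0.0), dt=0.01)
        assert (out.x, out.y, out.theta) == (5.0, 5.0, 1.0)
        assert out.t == pytest.approx(0.01)

    def test_uniform_flow_advances(self):
        prov = uniform_flow(10.0, 0.0)
        st = lv.LarvaState(x=5.0, y=5.0, theta=0.0)
        out = lv.step(st, prov, lv.LarvaParams(u_ell=0.0), dt=0.01)
        assert out.x == pytest.approx(5.1)

    def test_sphere_orbit_in_solid_body_rotation(self):
        om = 0.2
        prov = rotation_flow(om, 20.0, 15.0, domain_height=1e6,
                             domain_length=1e6)
        params = lv.LarvaParams(a=0.2, b=0.2, u_ell=0.0)
        st = lv.LarvaState(x=22.0, y=15.0, theta=0.3)
        rev = 2 * np.pi / om
        n = int(round(rev / 0.01))
        for _ in range(n):
            st = lv.step(st, prov, params, dt=0.01)
        r = np.hypot(st.x - 20.0, st.y - 15.0)
        assert r == pytest.approx(2.0, rel=0.01)
        # orientation advanced at omega_z / 2 = om
        assert (st.theta - 0.3) % (2 * np.pi) == pytest.approx(
            (om * rev) % (2 * np.pi), abs=0.02)


class TestCheckSettlement:
    def test_contact_below_gate_settles(self):
        sub = ff.SubstrateProfile.flat()
        st = lv.LarvaState(x=1.0, y=0.1, theta=0.0)
        assert lv.check_settlement(st, sub, (3.5, 0.0)) == "settled"

    def test_contact_above_gate_keeps_swimming(self):
        sub = ff.SubstrateProfile.flat()
        st = lv.LarvaState(x=1.0, y=0.1, theta=0.0)
        assert lv.check_settlement(st, sub, (5.0, 0.0)) == "swimming"

    def test_above_domain_exits(self):
        sub = ff.SubstrateProfile.flat()
        st = lv.LarvaState(x=1.0, y=35.0, theta=0.0)
        assert lv.check_settlement(st, sub, (0.0, 0.0)) == "exited"


class TestSeedLattice:
    def test_default_lattice_size(self, stokes_flow):
        assert lv.SimConfig().lattice_size == 19200
        states = lv.seed_lattice(lv.SimConfig(), stokes_flow)
        assert len(states) == 19200

    def test_single_state(self):
        cfg = lv.SimConfig(n_positions=1, n_orientations=1, n_phases=1)
        (st,) = lv.seed_lattice(cfg, 40.0)
        assert st.y == 10.0 and st.theta == 0.0 and st.t == 0.0

    def test_orientation_spacing(self):
        cfg = lv.SimConfig(n_positions=1, n_orientations=4, n_phases=1)
        states = lv.seed_lattice(cfg, 40.0)
        np.testing.assert_allclose(sorted(s.theta for s in states),
                                   [0, np.pi / 2, np.pi, 3 * np.pi / 2])

    def test_time_step_fraction_of_period(self, forcing):
        frac = 100.0 * lv.SimConfig().dt / forcing.T
        assert float(f"{frac:.2g}") == 0.18


class TestRunSimulation:
    CFG = dict(n_positions=4, n_orientations=8, n_phases=1, seed_height=5.0)

    def test_zero_field_passive_all_unresolved(self):
        prov = uniform_flow(0.0, 0.0, substrate=ff.SubstrateProfile.flat())
        res = lv.run_simulation(prov, lv.LarvaParams(u_ell=0.0),
                                lv.SimConfig(max_time=2.0, **self.CFG))
        assert res.fractions() == {"settled": 0.0, "exited": 0.0,
                                   "unresolved": 100.0}

    def test_fast_downward_flow_blocks_settlement(self):
        # passive agents, speed gate kept at the default 4 mm/s
        prov = uniform_flow(0.0, -6.0, substrate=ff.SubstrateProfile.flat())
        res = lv.run_simulation(prov, lv.LarvaParams(u_ell=0.0, sd_u=4.0),
                                lv.SimConfig(max_time=5.0, **self.CFG))
        assert res.settlement_fraction == 0.0
        # agents accumulate at the wall, sliding
        assert np.all(res.records["y_final"] < 0.2)

    def test_slow_downward_flow_settles_all(self):
        prov = uniform_flow(0.0, -2.0, substrate=ff.SubstrateProfile.flat())
        res = lv.run_simulation(prov, lv.LarvaParams(u_ell=0.0, sd_u=4.0),
                                lv.SimConfig(max_time=10.0, **self.CFG))
        assert res.settlement_fraction == 100.0

    def test_deterministic_repeat(self, stokes_flow):
        cfg = lv.SimConfig(n_positions=2, n_orientations=8, n_phases=2,
                           max_time=10.0)
        a = lv.run_simulation(stokes_flow, config=cfg)
        b = lv.run_simulation(stokes_flow, config=cfg)
        assert a.records.equals(b.records)

    def test_speed_gate_monotonicity(self):
        """Raising the settlement speed gate never loses settlers."""
        prov = uniform_flow(0.0, -3.5, substrate=ff.SubstrateProfile.flat())
        cfg = lv.SimConfig(max_time=5.0, **self.CFG)
        counts = []
        for sd in (3.0, 3.4, 4.0):  # gates 3.0, 3.4, 4.0 vs contact speed 3.5
            res = lv.run_simulation(prov, lv.LarvaParams(u_ell=0.0, sd_u=sd), cfg)
            counts.append(res.counts()["settled"])
        assert counts == sorted(counts)
        assert counts[0] == 0 and counts[-1] > 0

    def test_passive_rk4_limit_matches_tracer_advection(self, stokes_flow):
        cfg = lv.SimConfig(n_positions=1, n_orientations=1, n_phases=1,
                           seed_height=3.0, max_time=1.0, integrator="rk4")
        res = lv.run_simulation(stokes_flow, lv.LarvaParams(u_ell=0.0), cfg)
        x0 = res.records["x0"].iloc[0]
        tracks = ff.advect_tracers(stokes_flow, positions0=[[x0, 3.0]],
                                   duration=1.0, dt=0.01)
        last = tracks.data.iloc[-1]
        L = stokes_flow.domain_length
        assert res.records["x_final"].iloc[0] == pytest.approx(
            last["x"] % L, abs=1e-9)
        assert res.records["y_final"].iloc[0] == pytest.approx(last["y"], abs=1e-9)

    def test_exit_through_open_top(self):
        prov = uniform_flow(0.0, 5.0, substrate=ff.SubstrateProfile.flat(),
                            domain_height=8.0)
        res = lv.run_simulation(prov, lv.LarvaParams(u_ell=0.0),
                                lv.SimConfig(max_time=5.0, **self.CFG))
        assert res.fractions()["exited"] == 100.0


class TestJeffery:
    def test_tumbling_period_recovered(self):
        """Ellipse r = 5/3 in unit shear tumbles with period (2 pi) (r + 1/r)."""
        gamma, r = 1.0, 5.0 / 3.0
        prov = shear_flow(gamma, domain_height=1e6, domain_length=1e6)
        params = lv.LarvaParams(a=0.25, b=0.15, u_ell=0.0)
        expected = 2 * np.pi / gamma * (r + 1.0 / r)
        st = lv.LarvaState(x=0.0, y=100.0, theta=np.pi / 2)
        dt, t, th, unwrapped = 0.01, 0.0, st.theta, [st.theta]
        times = [0.0]
        while t < 1.2 * expected:
            st = lv.step(st, prov, params, dt=dt)
            t = st.t
            times.append(t)
            prev = unwrapped[-1]
            d = (st.theta - prev + np.pi) % (2 * np.pi) - np.pi
            unwrapped.append(prev + d)
        unwrapped = np.array(unwrapped)
        # theta decreases monotonically; find the 2 pi crossing
        target = unwrapped[0] - 2 * np.pi
        k = np.argmax(unwrapped <= target)
        f = (unwrapped[k - 1] - target) / (unwrapped[k - 1] - unwrapped[k])
        period = times[k - 1] + f * dt
        assert period == pytest.approx(expected, rel=0.01)

    def test_sphere_rotates_at_half_vorticity(self):
        """alpha = 0 gives dtheta/dt = omega_z / 2 for every orientation."""
        th = np.linspace(0, 2 * np.pi, 17)
        rate = lv._rotation_rate(th, -1.0, 0.0, 1.0, 0.0, 0.0, alpha=0.0)
        np.testing.assert_array_equal(rate, np.full_like(th, -0.5))


class TestTrajectory:
    def test_uniform_fast_flow_diagnostics(self):
        prov = uniform_flow(6.0, 0.0, substrate=ff.SubstrateProfile.flat(),
                            domain_height=50.0)
        traj = lv.run_trajectory(prov, lv.LarvaState(x=5.0, y=10.0, theta=0.0),
                                 config=lv.SimConfig(max_time=2.0))
        q, ratio, windows = lv.trajectory_diagnostics(traj, prov)
        np.testing.assert_allclose(ratio, 2.0)
        np.testing.assert_allclose(q, 0.0)
        assert windows == []

    def test_still_fluid_single_active_window(self):
        prov = uniform_flow(0.0, 0.0, substrate=ff.SubstrateProfile.flat(),
                            domain_height=50.0)
        traj = lv.run_trajectory(prov, lv.LarvaState(x=5.0, y=20.0, theta=0.0),
                                 config=lv.SimConfig(max_time=1.0))
        assert len(traj.active_windows) == 1
        a, b = traj.active_windows[0]
        assert (a, b) == (pytest.approx(traj.data["t"].iloc[0]),
                          pytest.approx(traj.data["t"].iloc[-1]))

    def test_cavity_q_sampled_along_path(self, ridged_flow):
        """Max sampled Q along a cavity-crossing path matches the analytic
        cavity-field Q at the sampled points."""
        import pandas as pd
        x = np.linspace(3.0, 9.5, 50)
        y = np.full(50, 1.25)
        t = np.linspace(2.5, 3.0, 50)  # around the reversal: cavity cell strong
        df = pd.DataFrame({"t": t, "x": x, "y": y,
                           "theta": 0.0, "u": 0.0, "v": 0.0,
                           "speed_ratio": 0.0, "q": 0.0, "status": "swimming"})
        traj = lv.Trajectory(data=df, params=lv.LarvaParams())
        q, _, _ = lv.trajectory_diagnostics(traj, ridged_flow)
        # independent route: Q from finite differences of the velocity field
        h = 1e-5
        dudx = (ridged_flow.velocity(x + h, y, t)[0]
                - ridged_flow.velocity(x - h, y, t)[0]) / (2 * h)
        dudy = (ridged_flow.velocity(x, y + h, t)[0]
                - ridged_flow.velocity(x, y - h, t)[0]) / (2 * h)
        dvdx = (ridged_flow.velocity(x + h, y, t)[1]
                - ridged_flow.velocity(x - h, y, t)[1]) / (2 * h)
        q_ref = dudx * (-dudx) - dudy * dvdx  # det(grad U), divergence-free
        np.testing.assert_allclose(q, q_ref, rtol=1e-4, atol=1e-6)
        assert q.max() > 0  # the path crosses the cavity vortex core
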