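"""Flow generation: forcing, Stokes layer, ridged cavities, grids, tracers, I/O."""

import numpy as np
import pytest

from larvaflow import flowfield as ff
from conftest import rotation_flow, uniform_flow


class TestForcing:
    @pytest.mark.parametrize("t,expected", [
        (0.0, 0.0),            # turning point at zero phase
        (1.375, 45.0),         # quarter period = peak
        (0.5, 24.3288),        # direct evaluation of 45 sin(2 pi 0.5 / 5.5)
    ])
    def test_free_stream_values(self, forcing, t, expected):
        assert ff.free_stream(forcing, t) == pytest.approx(expected, abs=1e-3)

    def test_free_stream_zero_mean_and_peak(self, forcing):
        t = np.linspace(0, forcing.T, 4000, endpoint=False)
        u = ff.free_stream(forcing, t)
        assert abs(u.mean()) < 1e-10 * forcing.U0
        assert u.max() == pytest.approx(forcing.U0, rel=1e-2)

    def test_invalid_forcing(self):
        with pytest.raises(ValueError):
            ff.OscillatoryForcing(U0=-1)
        with pytest.raises(ValueError):
            ff.OscillatoryForcing(T=0)


class TestReynolds:
    def test_values(self):
        assert ff.reynolds(1, 1, 1) == 1
        assert ff.reynolds(45, 91, 1.0) == pytest.approx(4095)
        assert ff.reynolds(30, 91, 0.85) == pytest.approx(3211.76, abs=0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ff.reynolds(0, 1, 1)


class TestSubstrate:
    def test_default_ridged_ratio(self):
        sub = ff.SubstrateProfile.ridged()
        assert sub.ridge_spacing / sub.ridge_height == 3
        assert set(np.unique(sub.elevation(np.linspace(0, 40, 801)))) \
            == {0.0, 2.5}

    def test_flat_elevation(self):
        sub = ff.SubstrateProfile.flat()
        assert np.all(sub.elevation(np.linspace(0, 40, 100)) == 0)

    def test_distance_to_solid_geometry(self):
        sub = ff.SubstrateProfile.ridged()  # ridge [0, 2.5], cavity (2.5, 10)
        assert sub.distance_to_solid(6.25, 1.0) == pytest.approx(1.0)   # floor
        assert sub.distance_to_solid(2.8, 1.0) == pytest.approx(0.3)    # flank
        assert sub.distance_to_solid(1.0, 3.0) == pytest.approx(0.5)    # top
        assert sub.distance_to_solid(1.0, 1.0) == 0.0                   # inside
        # corner: above cavity, diagonal to ridge corner
        assert sub.distance_to_solid(2.9, 2.8) == pytest.approx(np.hypot(0.4, 0.3))


class TestStokesLayer:
    def test_no_slip_at_wall(self, stokes_flow):
        for t in (0.0, 1.1, 2.7):
            u, v = stokes_flow.velocity(5.0, 0.0, t)
            assert u == 0.0 and v == 0.0

    def test_far_field_matches_free_stream(self, stokes_flow, forcing):
        y = 20 * stokes_flow.delta
        for t in (0.3, 1.3, 4.0):
            u, _ = stokes_flow.velocity(0.0, y, t)
            assert u == pytest.approx(ff.free_stream(forcing, t), rel=1e-6)

    def test_amplitude_at_delta(self, stokes_flow, forcing):
        # |1 - exp(-(1+i))| U0 = 0.8590 U0 from the complex amplitude
        t = np.linspace(0, forcing.T, 8000)
        u = np.array([stokes_flow.velocity(0.0, stokes_flow.delta, tt)[0]
                      for tt in t])
        expected = abs(1 - np.exp(-(1 + 1j))) * forcing.U0
        assert np.max(np.abs(u)) == pytest.approx(expected, rel=1e-4)

    def test_closed_form_everywhere(self, stokes_flow, forcing):
        """u equals the complex-amplitude solution at every sampled (y, t)."""
        om, d = forcing.omega, stokes_flow.delta
        y = np.linspace(0, 10, 37)
        for t in np.linspace(0, forcing.T, 11):
            u, _ = stokes_flow.velocity(0.0, y, t)
            ref = forcing.U0 * (np.sin(om * t)
                                - np.exp(-y / d) * np.sin(om * t - y / d))
            np.testing.assert_allclose(u, ref, rtol=1e-10, atol=1e-10)

    def test_time_periodicity(self, stokes_flow, forcing):
        y = np.linspace(0.05, 20, 50)
        u1, _ = stokes_flow.velocity(0.0, y, 1.234)
        u2, _ = stokes_flow.velocity(0.0, y, 1.234 + forcing.T)
        np.testing.assert_allclose(u1, u2, rtol=1e-9, atol=1e-9 * forcing.U0)

    def test_invalid_fluid(self):
        with pytest.raises(ValueError):
            ff.FluidProperties(nu=-1)


class TestRidgedCavity:
    def test_no_slip_on_all_solid_nodes(self, ridged_field_small):
        fld = ridged_field_small
        assert np.abs(fld.u[:, fld.solid_mask]).max() == 0.0
        assert np.abs(fld.v[:, fld.solid_mask]).max() == 0.0

    def test_peak_cavity_speed_calibration(self, ridged_flow):
        xs = np.linspace(2.5, 10.0, 301)
        ys = np.linspace(0.0, 2.5, 151)
        X, Y = np.meshgrid(xs, ys)
        best = 0.0
        for t in np.linspace(0, 5.5, 111):
            u, v = ridged_flow.velocity(X, Y, t)
            best = max(best, float(np.hypot(u, v).max()))
        assert best == pytest.approx(6.0, abs=0.5)

    def test_cavity_phasing_lags_free_stream(self, ridged_flow, forcing):
        """In-cavity speed is minimal at peak forcing, maximal at the reversal."""
        probe = (6.25, 0.625)  # quarter cavity height, off the vortex core
        speed = lambda t: float(np.hypot(*ridged_flow.velocity(*probe, t)))
        assert speed(forcing.T / 4.0) < 1e-9        # peak forcing
        assert speed(forcing.T / 2.0) > 1.0         # turning point

    def test_free_stream_recovered_above_blend(self, ridged_flow, forcing):
        for t in (0.4, 1.375, 3.2):
            u, v = ridged_flow.velocity(3.3, 29.0, t)
            assert u == pytest.approx(ff.free_stream(forcing, t),
                                      rel=1e-2, abs=1e-6)
            assert v == 0.0

    def test_grid_too_coarse_for_cavity(self):
        rc = ff.RidgedCavityFlow(substrate=ff.SubstrateProfile.ridged(0.25))
        with pytest.raises(ValueError, match="nodes across"):
            rc.to_grid(dx=0.2, nt=4)

    def test_gradients_consistent_with_finite_difference(self, ridged_flow):
        """Analytic gradient components match central differences of velocity."""
        pts = [(6.0, 1.2), (7.7, 0.6), (5.0, 4.0), (1.0, 3.1)]
        h, t = 1e-5, 0.9
        for (x, y) in pts:
            u0, v0, dudx, dudy, dvdx, dvdy = ridged_flow.sample(x, y, t)
            num_dudx = (ridged_flow.velocity(x + h, y, t)[0]
                        - ridged_flow.velocity(x - h, y, t)[0]) / (2 * h)
            num_dudy = (ridged_flow.velocity(x, y + h, t)[0]
                        - ridged_flow.velocity(x, y - h, t)[0]) / (2 * h)
            num_dvdx = (ridged_flow.velocity(x + h, y, t)[1]
                        - ridged_flow.velocity(x - h, y, t)[1]) / (2 * h)
            assert dudx == pytest.approx(num_dudx, abs=1e-5)
            assert dudy == pytest.approx(num_dudy, abs=1e-4)
            assert dvdx == pytest.approx(num_dvdx, abs=1e-5)


class TestGriddedField:
    def test_discrete_divergence_zero_interior(self, ridged_field_small):
        fld = ridged_field_small
        fl = fld.fluid_mask
        interior = (fl & np.roll(fl, 1, 0) & np.roll(fl, -1, 0)
                    & np.roll(fl, 1, 1) & np.roll(fl, -1, 1))
        interior[0, :] = interior[-1, :] = False
        bound = 1e-6 * fld.forcing.U0 / fld.dx
        for k in range(0, len(fld.t), 4):
            div = ((np.roll(fld.u[k], -1, 1) - np.roll(fld.u[k], 1, 1))
                   / (2 * fld.dx)
                   + (np.roll(fld.v[k], -1, 0) - np.roll(fld.v[k], 1, 0))
                   / (2 * fld.dy))
            assert np.abs(div[interior]).max() <= bound

    def test_sampled_field_periodic_in_time(self, flat_field_small):
        fld = flat_field_small
        x = np.array([2.0, 5.0])
        y = np.array([0.5, 3.0])
        u1, v1 = fld.velocity(x, y, 0.77)
        u2, v2 = fld.velocity(x, y, 0.77 + fld.period)
        np.testing.assert_allclose(u1, u2, rtol=1e-9, atol=1e-9)

    def test_top_of_domain_matches_forcing(self, flat_field_small):
        fld = flat_field_small
        # domain top is ~8 delta: free stream to within 1%
        for k in (2, 5, 9):
            expected = ff.free_stream(fld.forcing, fld.t[k])
            assert fld.u[k, -1, :].mean() == pytest.approx(
                expected, rel=1e-2, abs=0.05 * fld.forcing.U0)


class TestRegrid:
    def test_identity_regrid(self, flat_field_small):
        out = ff.regrid_field(flat_field_small, flat_field_small.dx)
        np.testing.assert_allclose(out.u, flat_field_small.u, atol=1e-12)

    def test_uniform_preserved_and_linear_exact(self):
        x = np.arange(0, 2.01, 0.5)
        y = np.arange(0, 2.01, 0.5)
        t = np.array([0.0])
        YY = np.broadcast_to(y[:, None], (len(y), len(x)))
        u = np.stack([3.0 * YY])  # linear in y
        v = np.full_like(u, 7.0)  # uniform
        fld = ff.VelocityField(x=x, y=y, t=t, u=u, v=v,
                               solid_mask=np.zeros((len(y), len(x)), bool),
                               periodic_x=False)
        out = ff.regrid_field(fld, 0.25)
        YY2 = np.broadcast_to(out.y[:, None], out.u.shape[1:])
        np.testing.assert_allclose(out.u[0], 3.0 * YY2, atol=1e-12)
        np.testing.assert_allclose(out.v[0], 7.0, atol=1e-12)

    def test_bad_dx(self, flat_field_small):
        with pytest.raises(ValueError):
            ff.regrid_field(flat_field_small, 100.0)
        with pytest.raises(ValueError):
            ff.regrid_field(flat_field_small, -0.1)


class TestAdvectTracers:
    def test_stationary_in_zero_field(self):
        prov = uniform_flow(0.0, 0.0)
        tracks = ff.advect_tracers(prov, positions0=[[5.0, 5.0]], duration=1.0)
        assert np.allclose(tracks.data["x"], 5.0)
        assert np.allclose(tracks.data["y"], 5.0)

    def test_orbit_radius_conserved(self):
        prov = rotation_flow(0.5, 20.0, 15.0, domain_height=1e6)
        rev = 2 * np.pi / 0.5
        tracks = ff.advect_tracers(prov, positions0=[[22.0, 15.0]],
                                   duration=rev, dt=0.01)
        r = np.hypot(tracks.data["x"] - 20.0, tracks.data["y"] - 15.0)
        assert np.abs(r - 2.0).max() < 0.002  # 0.1% of radius

    def test_same_seed_identical(self, stokes_flow):
        a = ff.advect_tracers(stokes_flow, n=10, seed=3, duration=0.2)
        b = ff.advect_tracers(stokes_flow, n=10, seed=3, duration=0.2)
        assert a.data.equals(b.data)

    def test_seed_inside_solid_rejected(self, stokes_flow):
        with pytest.raises(ValueError, match="solid"):
            ff.advect_tracers(stokes_flow, positions0=[[5.0, -1.0]], duration=0.1)


class TestRenderFrames:
    def test_stationary_particle_and_argmax(self):
        import pandas as pd
        n = 5
        df = pd.DataFrame({"particle": 0, "t": np.arange(n) / 90.0,
                           "x": 10 * 0.031, "y": 20 * 0.031})
        stack = ff.render_frames(ff.ParticleTracks(df), ff.RenderOptics())
        assert np.allclose(stack.frames[0], stack.frames[-1])
        r, c = np.unravel_index(stack.frames[0].argmax(), stack.frames[0].shape)
        assert (r, c) == (20, 10)

    def test_moving_particle_argmax_advances(self):
        import pandas as pd
        n = 6
        df = pd.DataFrame({"particle": 0, "t": np.arange(n) / 90.0,
                           "x": (10 + 2 * np.arange(n)) * 0.031, "y": 15 * 0.031})
        stack = ff.render_frames(ff.ParticleTracks(df), ff.RenderOptics(
            shape=(30, 40)))
        cols = [np.unravel_index(f.argmax(), f.shape)[1] for f in stack.frames]
        assert np.all(np.diff(cols) == 2)

    def test_pure_noise_mean(self):
        import pandas as pd
        df = pd.DataFrame({"particle": [], "t": [], "x": [], "y": []})
        # zero particles: frames defined by explicit shape and times via fps
        df = pd.DataFrame({"particle": [0, 0], "t": [0.0, 1 / 90.0],
                           "x": [-1.0, -1.0], "y": [-1.0, -1.0]})  # off-frame
        stack = ff.render_frames(ff.ParticleTracks(df), ff.RenderOptics(
            shape=(50, 50), noise_level=2.0), seed=5)
        assert stack.frames.mean() == pytest.approx(2.0, rel=0.05)

    def test_fps_mismatch_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"particle": 0, "t": np.arange(4) * 0.1,
                           "x": 1.0, "y": 1.0})
        with pytest.raises(ValueError, match="fps"):
            ff.render_frames(ff.ParticleTracks(df), ff.RenderOptics())


class TestFieldIO:
    def test_round_trip_bitwise(self, flat_field_small, tmp_path):
        p = tmp_path / "f.h5"
        ff.write_field(flat_field_small, p)
        back = ff.read_field(p)
        assert np.array_equal(back.u, flat_field_small.u)
        assert np.array_equal(back.v, flat_field_small.v)
        assert np.array_equal(back.solid_mask, flat_field_small.solid_mask)
        assert back.forcing == flat_field_small.forcing
        assert back.substrate == flat_field_small.substrate

    def test_missing_dataset_named(self, flat_field_small, tmp_path):
        import h5py
        p = tmp_path / "f.h5"
        ff.write_field(flat_field_small, p)
        with h5py.File(p, "a") as f:
            del f["u"]
        with pytest.raises(ValueError, match="'/u'"):
            ff.read_field(p)

    def test_minimal_hand_written_archive(self, tmp_path):
        import h5py
        p = tmp_path / "mini.h5"
        u = np.arange(8, dtype=float).reshape(2, 2, 2)
        with h5py.File(p, "w") as f:
            f["x"] = [0.0, 1.0]
            f["y"] = [0.0, 1.0]
            f["t"] = [0.0, 0.5]
            f["u"] = u
            f["v"] = -u
            f["solid_mask"] = np.zeros((2, 2), dtype=np.uint8)
        fld = ff.read_field(p)
        assert np.array_equal(fld.u, u)
        assert np.array_equal(fld.v, -u)

    def test_csv_slice_export(self, flat_field_small, tmp_path):
        import pandas as pd
        p = tmp_path / "slice.csv"
        ff.export_slice_csv(flat_field_small, 0.0, p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["t", "x", "y", "u", "v"]
        assert len(df) == flat_field_small.u[0].size
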