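import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

from larvaflow.flowfield import (CallableFlow, FluidProperties,  # noqa: E402
                                 OscillatoryForcing, RidgedCavityFlow,
                                 StokesLayerFlow, SubstrateProfile)


@pytest.fixture(scope="session")
def forcing():
    return OscillatoryForcing()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def stokes_flow():
    return StokesLayerFlow()


@pytest.fixture(scope="session")
def ridged_flow():
    return RidgedCavityFlow()


@pytest.fixture(scope="session")
def flat_field_small():
    """Coarse gridded flat-substrate Stokes field (10 x 10 mm, dx 0.1)."""
    return StokesLayerFlow(domain_height=10.0, domain_length=10.0).to_grid(
        dx=0.1, nt=16)


@pytest.fixture(scope="session")
def ridged_field_small():
    """Coarse gridded ridged field (default 2.5 mm ridges, 10 mm tall domain)."""
    return RidgedCavityFlow(domain_height=10.0).to_grid(dx=0.1, nt=16)


def uniform_flow(u0, v0, **kw):
    return CallableFlow(lambda x, y, t: (np.full_like(np.asarray(x, float), u0),
                                         np.full_like(np.asarray(y, float), v0)),
                        lambda x, y, t: (0.0, 0.0, 0.0, 0.0), **kw)


def shear_flow(gamma, **kw):
    """Simple shear u = gamma * y, v = 0."""
    return CallableFlow(
        lambda x, y, t: (gamma * np.asarray(y, float),
                         np.zeros_like(np.asarray(y, float))),
        lambda x, y, t: (0.0, gamma, 0.0, 0.0), **kw)


def rotation_flow(omega, xc, yc, **kw):
    """Solid-body rotation with angular velocity omega about (xc, yc)."""
    return CallableFlow(
        lambda x, y, t: (-omega * (np.asarray(y, float) - yc),
                         omega * (np.asarray(x, float) - xc)),
        lambda x, y, t: (0.0, -omega, omega, 0.0), **kw)


def ptv_recovery_rel_rms(seed=42, n_frames=40, fps=90.0,
                         threshold=0.25, max_disp=12.0, dx=0.5):
    """Full advect -> render -> detect -> link -> grid chain on the default
    Stokes-layer field around the flow reversal; returns the relative RMS
    between the PTV-gridded u and the analytic field sampled at the same
    link midpoints and binned identically (cells with >= 5 samples).

    Tracers are seeded on horizontal strata (as in a well-seeded laser-sheet
    experiment) so that spots stay resolvable: particles sharing a stratum
    share the same u(y) and keep their separation, and strata are farther
    apart vertically than the spot footprint.
    """
    import pandas as pd
    from larvaflow import flowfield as ff, ptv
    from larvaflow._numerics import rk4_step

    flow = StokesLayerFlow(domain_height=6.0, domain_length=30.0)
    T = flow.forcing.T
    t_start = T / 2.0 - 0.5 * n_frames / fps
    rng = np.random.default_rng(seed)
    # strata spacing (0.3 mm ~ 9.7 px) exceeds the largest frame-to-frame
    # displacement, so the true link is always the nearest candidate
    strata = 0.2 + 0.3 * np.arange(17)
    per = 10                                  # tracers per stratum
    y = np.repeat(strata, per)
    # left margin of 8 mm: the boundary layer leads the free stream, so
    # near-wall tracers drift several mm leftward around the reversal
    x = (8.0 + (np.tile(np.arange(per), len(strata))
                + rng.uniform(0.0, 0.6, y.size)) * (18.0 / per))
    n = y.size
    dt = 1.0 / fps
    rows = []
    for k in range(n_frames):
        rows.extend(zip(range(n), np.full(n, k * dt), x.copy(), y.copy()))
        x, y = rk4_step(lambda xx, yy, tt: flow.velocity(xx, yy, tt + t_start),
                        x, y, k * dt, dt)
    tracks = ff.ParticleTracks(pd.DataFrame(
        rows, columns=["particle", "t", "x", "y"]))
    stack = ff.render_frames(tracks, ff.RenderOptics(noise_level=0.5), seed=1)
    dets = [ptv.detect_particles(f, ptv.DetectionParams(
        intensity_threshold=threshold)) for f in stack.frames]
    linked = ptv.link_tracks(dets, ptv.LinkingParams(max_disp=max_disp),
                             fps, 0.031)
    bounds = (2.0, 28.0, 0.0, 5.5)
    out = ptv.grid_velocities(linked, {"win": (0.0, n_frames / fps)}, dx=dx,
                              bounds=bounds)
    # reference: analytic u at the recovered link midpoints, binned the same
    d = linked.data.sort_values(["particle", "t"])
    same = d["particle"].to_numpy()[1:] == d["particle"].to_numpy()[:-1]
    mx = 0.5 * (d["x"].to_numpy()[1:] + d["x"].to_numpy()[:-1])[same]
    my = 0.5 * (d["y"].to_numpy()[1:] + d["y"].to_numpy()[:-1])[same]
    mt = 0.5 * (d["t"].to_numpy()[1:] + d["t"].to_numpy()[:-1])[same]
    u_ref, _ = flow.velocity(mx, my, mt + t_start)
    nx, ny = len(out.x), len(out.y)
    ci = np.clip(np.round((mx - bounds[0]) / dx).astype(int), 0, nx - 1)
    cj = np.clip(np.round((my - bounds[2]) / dx).astype(int), 0, ny - 1)
    ref_sum = np.zeros((ny, nx))
    ref_cnt = np.zeros((ny, nx), dtype=int)
    np.add.at(ref_sum, (cj, ci), u_ref)
    np.add.at(ref_cnt, (cj, ci), 1)
    pop = (out.counts[0] >= 5) & (ref_cnt >= 5)
    assert pop.sum() > 50
    ref = ref_sum[pop] / ref_cnt[pop]
    err = out.u[0][pop] - ref
    return float(np.sqrt(np.mean(err ** 2)) / np.sqrt(np.mean(ref ** 2)))
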