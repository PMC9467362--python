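"""Synthetic oscillatory boundary-layer flow fields over flat and ridged substrates.

This module is the synthetic-data stage of the package.  It provides

* :class:`SubstrateProfile` -- flat or rectangular-ridged substrate geometry,
* :class:`OscillatoryForcing` / :class:`FluidProperties` -- the sinusoidal
  free-stream forcing and seawater properties,
* analytic flow providers: :class:`StokesLayerFlow` (the exact oscillatory
  Stokes boundary layer over a flat wall) and :class:`RidgedCavityFlow`
  (a streamfunction-composed stand-in for the recirculating flow between
  millimetre-scale ridges),
* :class:`VelocityField` -- time-resolved gridded (u, v) with a solid mask,
* passive-tracer advection, synthetic PTV frame rendering, and HDF5/CSV I/O.

Units are millimetres and seconds throughout: lengths mm, velocities mm/s,
the Q-criterion (downstream) s^-2.  x is streamwise, y vertical with y = 0
at the substrate base.  Generated fields are periodic in x and in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Optional

import numpy as np

from ._numerics import rk4_step, smoothstep

__all__ = [
    "SubstrateProfile",
    "OscillatoryForcing",
    "FluidProperties",
    "VelocityField",
    "ParticleTracks",
    "FrameStack",
    "RenderOptics",
    "StokesLayerFlow",
    "RidgedCavityFlow",
    "CallableFlow",
    "free_stream",
    "reynolds",
    "regrid_field",
    "advect_tracers",
    "render_frames",
    "write_field",
    "read_field",
    "export_slice_csv",
]

#: default grid spacing for gridded velocity fields [mm]
DEFAULT_DX = 0.05
#: default number of stored time slices per forcing period (FFT-friendly)
DEFAULT_NT = 64


# ---------------------------------------------------------------------------
# geometry and forcing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstrateProfile:
    """Substrate geometry: a flat floor or rectangular ridges on a floor.

    Ridges are ``ridge_height`` tall, ``ridge_width`` wide, separated by
    ``ridge_spacing`` edge-to-edge; the pattern repeats with period
    ``ridge_width + ridge_spacing`` along x.  The default ridged geometry
    (2.5 mm ridges, 7.5 mm gaps) has a spacing-to-height ratio of 3.
    Within each period, the ridge occupies local x in [0, ridge_width] and
    the cavity occupies (ridge_width, period).
    """

    kind: str = "flat"
    ridge_height: float = 2.5
    ridge_spacing: float = 7.5
    ridge_width: float = 2.5
    n_ridges: int = 4

    def __post_init__(self):
        if self.kind not in ("flat", "ridged"):
            raise ValueError(f"unknown substrate kind {self.kind!r}")
        if self.kind == "ridged":
            if min(self.ridge_height, self.ridge_spacing, self.ridge_width) <= 0:
                raise ValueError("ridge dimensions must be positive")

    @classmethod
    def flat(cls) -> "SubstrateProfile":
        return cls(kind="flat")

    @classmethod
    def ridged(cls, height: float = 2.5, spacing_to_height: float = 3.0,
               width: Optional[float] = None, n_ridges: int = 4) -> "SubstrateProfile":
        """Ridged substrate with a given height and spacing-to-height ratio.

        Ridge width defaults to the ridge height (square cross-section).
        """
        return cls(kind="ridged", ridge_height=height,
                   ridge_spacing=spacing_to_height * height,
                   ridge_width=height if width is None else width,
                   n_ridges=n_ridges)

    @property
    def period(self) -> float:
        """Ridge pattern period along x [mm]."""
        if self.kind == "flat":
            raise ValueError("flat substrate has no ridge period")
        return self.ridge_width + self.ridge_spacing

    @property
    def domain_length(self) -> float:
        """Default periodic domain length [mm]: 4 ridge periods, or 40 mm flat."""
        return 40.0 if self.kind == "flat" else self.n_ridges * self.period

    def elevation(self, x):
        """Surface height above the floor at streamwise position(s) x [mm]."""
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(x)
        xt = np.mod(x, self.period)
        return np.where(xt <= self.ridge_width, self.ridge_height, 0.0)

    def is_solid(self, x, y):
        """Boolean: point(s) inside (or on) the solid substrate."""
        y = np.asarray(y, dtype=float)
        return y <= self.elevation(x)

    def distance_to_solid(self, x, y):
        """Euclidean distance from point(s) to the nearest solid surface [mm].

        Zero for points inside the solid.  Vectorized; accounts for the
        periodic ridge pattern.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "flat":
            return np.maximum(y, 0.0)
        p, w, h = self.period, self.ridge_width, self.ridge_height
        xt = np.mod(x, p)
        dxr = np.minimum(np.maximum(xt - w, 0.0), np.maximum(p - xt, 0.0))
        dyr = np.maximum(y - h, 0.0)
        d = np.minimum(np.maximum(y, 0.0), np.hypot(dxr, dyr))
        inside = (y <= 0.0) | ((y <= h) & (xt <= w))
        return np.where(inside, 0.0, d)

    def in_cavity(self, x, y):
        """Boolean: point(s) inside an inter-ridge cavity (fluid side)."""
        if self.kind == "flat":
            return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape, bool)
        xt = np.mod(np.asarray(x, dtype=float), self.period)
        y = np.asarray(y, dtype=float)
        return (xt > self.ridge_width) & (y > 0.0) & (y < self.ridge_height)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "ridge_height": self.ridge_height,
            "ridge_spacing": self.ridge_spacing, "ridge_width": self.ridge_width,
            "n_ridges": self.n_ridges})

    @classmethod
    def from_json(cls, s: str) -> "SubstrateProfile":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class OscillatoryForcing:
    """Sinusoidal free-stream forcing: U(t) = U0 sin(2 pi t / T + phase0).

    Defaults (peak speed 45 mm/s, period 5.5 s) emulate wave-driven flow in
    shallow reef habitats.  phase0 = 0 puts a turning point at t = 0.
    """

    U0: float = 45.0     # peak free-stream speed [mm/s]
    T: float = 5.5       # oscillation period [s]
    phase0: float = 0.0  # [rad]

    def __post_init__(self):
        if self.U0 <= 0 or self.T <= 0:
            raise ValueError("U0 and T must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency 2 pi / T [rad/s]."""
        return 2.0 * np.pi / self.T

    def __call__(self, t):
        return free_stream(self, t)


def free_stream(forcing: OscillatoryForcing, t):
    """Free-stream speed U0 sin(omega t + phase0) at time(s) t [mm/s]."""
    t = np.asarray(t, dtype=float)
    out = forcing.U0 * np.sin(forcing.omega * t + forcing.phase0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FluidProperties:
    """Seawater properties.  nu defaults to 0.85 mm^2/s (approx. 27.5 C)."""

    nu: float = 0.85  # kinematic viscosity [mm^2/s]

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("kinematic viscosity must be positive")

    def stokes_delta(self, forcing: OscillatoryForcing) -> float:
        """Oscillatory boundary-layer thickness delta = sqrt(2 nu / omega) [mm]."""
        return float(np.sqrt(2.0 * self.nu / forcing.omega))


def reynolds(U: float, L: float, nu: float) -> float:
    """Reynolds number Re = U L / nu (U in mm/s, L in mm, nu in mm^2/s)."""
    if U <= 0 or L <= 0 or nu <= 0:
        raise ValueError("U, L and nu must all be positive")
    return U * L / nu


# ---------------------------------------------------------------------------
# analytic flow providers
# ---------------------------------------------------------------------------

class StokesLayerFlow:
    """Exact oscillatory Stokes boundary layer over a flat no-slip wall.

    u(y, t) = U0 [sin(wt) - exp(-y/delta) sin(wt - y/delta)],  v = 0,
    with delta = sqrt(2 nu / omega).  This is an exact solution of the
    Navier-Stokes equations and stands in for the measured laminar
    flat-substrate boundary layer.
    """

    provider = "analytic"

    def __init__(self, forcing: OscillatoryForcing = OscillatoryForcing(),
                 fluid: FluidProperties = FluidProperties(),
                 substrate: Optional[SubstrateProfile] = None,
                 domain_height: float = 30.0,
                 domain_length: Optional[float] = None):
        substrate = substrate or SubstrateProfile.flat()
        if substrate.kind != "flat":
            raise ValueError("StokesLayerFlow requires a flat substrate")
        self.forcing = forcing
        self.fluid = fluid
        self.substrate = substrate
        self.domain_height = float(domain_height)
        self.domain_length = float(domain_length if domain_length is not None
                                   else substrate.domain_length)
        self.delta = fluid.stokes_delta(forcing)
        self._k = (1.0 + 1.0j) / self.delta

    # -- complex-amplitude building blocks ---------------------------------
    def _phase(self, t):
        return np.exp(1j * (self.forcing.omega * np.asarray(t, dtype=float)
                            + self.forcing.phase0))

    def _u_profile(self, y, t):
        """u at height y above the wall (y >= 0)."""
        y = np.asarray(y, dtype=float)
        E = self._phase(t)
        u = self.forcing.U0 * np.imag(E * (1.0 - np.exp(-self._k * np.maximum(y, 0.0))))
        return np.where(y < 0, 0.0, u)

    def _dudy_profile(self, y, t):
        y = np.asarray(y, dtype=float)
        E = self._phase(t)
        g = self.forcing.U0 * np.imag(E * self._k * np.exp(-self._k * np.maximum(y, 0.0)))
        return np.where(y < 0, 0.0, g)

    def _psi_profile(self, y, t):
        """Streamfunction psi(y, t) with psi(0) = 0 (psi' = u)."""
        y = np.asarray(y, dtype=float)
        E = self._phase(t)
        yp = np.maximum(y, 0.0)
        psi = self.forcing.U0 * np.imag(
            E * (yp - (1.0 - np.exp(-self._k * yp)) / self._k))
        return np.where(y < 0, 0.0, psi)

    # -- provider interface -------------------------------------------------
    def velocity(self, x, y, t):
        u = self._u_profile(y, t)
        return u, np.zeros_like(u)

    def gradients(self, x, y, t):
        """(du/dx, du/dy, dv/dx, dv/dy) at the given point(s)."""
        g = self._dudy_profile(y, t)
        z = np.zeros_like(g)
        return z, g, z.copy(), z.copy()

    def sample(self, x, y, t):
        """(u, v, du/dx, du/dy, dv/dx, dv/dy) in one call."""
        y = np.asarray(y, dtype=float)
        E = self._phase(t)
        ek = np.exp(-self._k * np.maximum(y, 0.0))
        u = self.forcing.U0 * np.imag(E * (1.0 - ek))
        g = self.forcing.U0 * np.imag(E * self._k * ek)
        wet = y >= 0
        u = np.where(wet, u, 0.0)
        g = np.where(wet, g, 0.0)
        z = np.zeros_like(u)
        return u, z, z.copy(), g, z.copy(), z.copy()

    def streamfunction(self, x, y, t):
        return self._psi_profile(y, t)

    def to_grid(self, dx: float = DEFAULT_DX, nt: int = DEFAULT_NT,
                domain_height: Optional[float] = None,
                domain_length: Optional[float] = None) -> "VelocityField":
        return _grid_from_provider(self, dx, nt,
                                   domain_height or self.domain_height,
                                   domain_length or self.domain_length)


class RidgedCavityFlow:
    """Streamfunction-composed oscillatory flow over rectangular ridges.

    Above the ridge-crest plane the field is a Stokes layer referenced to the
    crest plane; inside each inter-ridge cavity a single no-slip recirculation
    cell psi = A(t) sin^2(pi X / s) sin^2(pi Y / h) whose amplitude tracks the
    magnitude of the free stream (optionally phase-lagged).  The two pieces are
    blended smoothly across the crest plane over ``blend_thickness``.  Both
    pieces derive from a streamfunction, so the field is divergence-free and
    vanishes on all solid surfaces.

    The cavity gain is calibrated so that the peak in-cavity speed equals
    ``peak_cavity_speed``; the default, 2.4 mm/s per mm of ridge height,
    gives 6 mm/s for the 2.5 mm ridges (matching the observed in-cavity
    speed range) and scales self-similarly for other ridge heights.

    The cavity amplitude lags the free stream by ``phase_lag`` (default a
    quarter period): the sheltered in-cavity flow is slowest while the free
    stream peaks and fastest around the flow reversal, when the decelerating
    outer flow washes through the gaps.  This reproduces the observed
    phasing in which the near-substrate speed between ridges reaches its
    minimum during the peak-flow phase (the opposite of a flat substrate).
    """

    provider = "analytic"

    def __init__(self, forcing: OscillatoryForcing = OscillatoryForcing(),
                 fluid: FluidProperties = FluidProperties(),
                 substrate: Optional[SubstrateProfile] = None,
                 cavity_gain: Optional[float] = None,
                 phase_lag: Optional[float] = None,
                 blend_thickness: float = 0.1,
                 peak_cavity_speed: Optional[float] = None,
                 domain_height: float = 30.0,
                 domain_length: Optional[float] = None):
        substrate = substrate or SubstrateProfile.ridged()
        if substrate.kind != "ridged":
            raise ValueError("RidgedCavityFlow requires a ridged substrate")
        self.forcing = forcing
        self.fluid = fluid
        self.substrate = substrate
        self.phase_lag = float(forcing.T / 4.0 if phase_lag is None else phase_lag)
        self.blend_thickness = float(blend_thickness)
        self.domain_height = float(domain_height)
        self.domain_length = float(domain_length if domain_length is not None
                                   else substrate.domain_length)
        self.delta = fluid.stokes_delta(forcing)
        self._k = (1.0 + 1.0j) / self.delta
        h = substrate.ridge_height
        if peak_cavity_speed is None:
            peak_cavity_speed = 2.4 * h
        self.peak_cavity_speed = float(peak_cavity_speed)
        # peak in-cavity speed of the sin^2 cell is A_peak * pi / h
        if cavity_gain is None:
            cavity_gain = self.peak_cavity_speed * h / (np.pi * forcing.U0)
        self.cavity_gain = float(cavity_gain)  # [mm]: psi amplitude per unit U

    # -- pieces -------------------------------------------------------------
    def _amplitude(self, t):
        """Cavity streamfunction amplitude A(t) [mm^2/s]."""
        return self.cavity_gain * np.abs(
            free_stream(self.forcing, np.asarray(t, dtype=float) - self.phase_lag))

    def _blend(self, Y):
        """Blend weight w(Y) = smoothstep(Y / bt) and its first two derivatives."""
        bt = self.blend_thickness
        z = Y / bt
        w = smoothstep(z)
        inside = (z > 0.0) & (z < 1.0)
        w1 = np.where(inside, (6.0 * z - 6.0 * z * z) / bt, 0.0)
        w2 = np.where(inside, (6.0 - 12.0 * z) / (bt * bt), 0.0)
        return w, w1, w2

    def sample(self, x, y, t):
        """(u, v, du/dx, du/dy, dv/dx, dv/dy) at the given point(s)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sub = self.substrate
        h, s, w_r, p = (sub.ridge_height, sub.ridge_spacing,
                        sub.ridge_width, sub.period)
        xt = np.mod(x, p)
        E = np.exp(1j * (self.forcing.omega * np.asarray(t, dtype=float)
                         + self.forcing.phase0))

        # --- above the crest plane: blended Stokes layer (y-dependent only)
        Y = np.maximum(y - h, 0.0)
        ek = np.exp(-self._k * Y)
        us = self.forcing.U0 * np.imag(E * (1.0 - ek))
        dus = self.forcing.U0 * np.imag(E * self._k * ek)
        psis = self.forcing.U0 * np.imag(E * (Y - (1.0 - ek) / self._k))
        wb, wb1, wb2 = self._blend(Y)
        # u = d/dY (psi_s * w) keeps the blended field divergence-free
        u_ab = us * wb + psis * wb1
        du_ab = dus * wb + 2.0 * us * wb1 + psis * wb2

        # --- inside the cavities: sin^2 recirculation cell
        A = self._amplitude(t)
        X = xt - w_r
        fX = np.sin(np.pi * X / s) ** 2
        f1 = (np.pi / s) * np.sin(2.0 * np.pi * X / s)
        f2 = (2.0 * np.pi ** 2 / s ** 2) * np.cos(2.0 * np.pi * X / s)
        gY = np.sin(np.pi * y / h) ** 2
        g1 = (np.pi / h) * np.sin(2.0 * np.pi * y / h)
        g2 = (2.0 * np.pi ** 2 / h ** 2) * np.cos(2.0 * np.pi * y / h)
        u_cav = A * fX * g1
        v_cav = -A * f1 * gY
        dudx_c = A * f1 * g1
        dudy_c = A * fX * g2
        dvdx_c = -A * f2 * gY
        dvdy_c = -A * f1 * g1

        above = y >= h
        in_cav = (~above) & (xt > w_r) & (y > 0.0)
        solid = sub.is_solid(x, y)

        zero = np.zeros(np.broadcast(x, y).shape)
        u = np.select([solid, above, in_cav], [zero, u_ab, u_cav], 0.0)
        v = np.select([solid, above, in_cav], [zero, zero, v_cav], 0.0)
        dudx = np.select([solid, above, in_cav], [zero, zero, dudx_c], 0.0)
        dudy = np.select([solid, above, in_cav], [zero, du_ab, dudy_c], 0.0)
        dvdx = np.select([solid, above, in_cav], [zero, zero, dvdx_c], 0.0)
        dvdy = np.select([solid, above, in_cav], [zero, zero, dvdy_c], 0.0)
        return u, v, dudx, dudy, dvdx, dvdy

    def velocity(self, x, y, t):
        out = self.sample(x, y, t)
        return out[0], out[1]

    def gradients(self, x, y, t):
        return self.sample(x, y, t)[2:]

    def streamfunction(self, x, y, t):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sub = self.substrate
        h, s, w_r, p = (sub.ridge_height, sub.ridge_spacing,
                        sub.ridge_width, sub.period)
        xt = np.mod(x, p)
        E = np.exp(1j * (self.forcing.omega * np.asarray(t, dtype=float)
                         + self.forcing.phase0))
        Y = np.maximum(y - h, 0.0)
        psis = self.forcing.U0 * np.imag(
            E * (Y - (1.0 - np.exp(-self._k * Y)) / self._k))
        wb, _, _ = self._blend(Y)
        psi_ab = psis * wb
        A = self._amplitude(t)
        psi_cav = A * np.sin(np.pi * (xt - w_r) / s) ** 2 * np.sin(np.pi * y / h) ** 2
        above = y >= h
        in_cav = (~above) & (xt > w_r) & (y > 0.0)
        solid = sub.is_solid(x, y)
        zero = np.zeros(np.broadcast(x, y).shape)
        return np.select([solid, above, in_cav], [zero, psi_ab, psi_cav], 0.0)

    def to_grid(self, dx: float = DEFAULT_DX, nt: int = DEFAULT_NT,
                domain_height: Optional[float] = None,
                domain_length: Optional[float] = None) -> "VelocityField":
        ncav = self.substrate.ridge_spacing / dx
        if ncav < 8:
            raise ValueError(
                f"grid spacing {dx} mm leaves only {ncav:.1f} nodes across a "
                f"{self.substrate.ridge_spacing} mm cavity (need >= 8)")
        return _grid_from_provider(self, dx, nt,
                                   domain_height or self.domain_height,
                                   domain_length or self.domain_length)


class CallableFlow:
    """Analytic flow provider built from user-supplied callables.

    ``velocity_fn(x, y, t) -> (u, v)`` and optionally
    ``gradients_fn(x, y, t) -> (dudx, dudy, dvdx, dvdy)``.  Useful for tests
    and for idealized flows (uniform flow, simple shear, solid-body rotation).
    """

    provider = "analytic"

    def __init__(self, velocity_fn: Callable, gradients_fn: Optional[Callable] = None,
                 substrate: Optional[SubstrateProfile] = None,
                 forcing: Optional[OscillatoryForcing] = None,
                 domain_height: float = 30.0, domain_length: float = 40.0):
        self._vel = velocity_fn
        self._grad = gradients_fn
        self.substrate = substrate or SubstrateProfile.flat()
        self.forcing = forcing
        self.domain_height = float(domain_height)
        self.domain_length = float(domain_length)

    def velocity(self, x, y, t):
        u, v = self._vel(x, y, t)
        shape = np.broadcast(np.asarray(x), np.asarray(y)).shape
        return np.broadcast_to(np.asarray(u, float), shape).copy(), \
            np.broadcast_to(np.asarray(v, float), shape).copy()

    def gradients(self, x, y, t):
        shape = np.broadcast(np.asarray(x), np.asarray(y)).shape
        if self._grad is None:
            z = np.zeros(shape)
            return z, z.copy(), z.copy(), z.copy()
        return tuple(np.broadcast_to(np.asarray(g, float), shape).copy()
                     for g in self._grad(x, y, t))

    def sample(self, x, y, t):
        return (*self.velocity(x, y, t), *self.gradients(x, y, t))


# ---------------------------------------------------------------------------
# gridded fields
# ---------------------------------------------------------------------------

@dataclass
class VelocityField:
    """Time-resolved 2D gridded velocity field with a solid mask.

    Arrays ``u`` and ``v`` have shape (nt, ny, nx) on uniform coordinates
    ``x`` (periodic) and ``y``; ``solid_mask`` is (ny, nx).  Time slices span
    one forcing period; sampling interpolates linearly in (periodic) time and
    bilinearly in space.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    solid_mask: np.ndarray
    forcing: Optional[OscillatoryForcing] = None
    substrate: Optional[SubstrateProfile] = None
    nu: Optional[float] = None
    provider: str = "gridded"
    periodic_x: bool = True
    attrs: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != (len(self.t), len(self.y), len(self.x)):
            raise ValueError(f"u has shape {self.u.shape}, expected "
                             f"{(len(self.t), len(self.y), len(self.x))}")
        if self.v.shape != self.u.shape:
            raise ValueError("u and v shapes differ")
        if self.solid_mask.shape != self.u.shape[1:]:
            raise ValueError("solid_mask shape does not match the grid")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if len(self.x) > 1 else np.inf

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if len(self.y) > 1 else np.inf

    @property
    def period(self) -> float:
        """Temporal period covered by the stored slices [s]."""
        if self.forcing is not None:
            return self.forcing.T
        nt = len(self.t)
        return float(self.t[-1] - self.t[0]) * nt / max(nt - 1, 1)

    @property
    def fluid_mask(self) -> np.ndarray:
        return ~self.solid_mask

    @property
    def domain_length(self) -> float:
        return float(self.x[0] + len(self.x) * self.dx) if self.periodic_x \
            else float(self.x[-1])

    @property
    def domain_height(self) -> float:
        return float(self.y[-1])

    # -- interpolation -------------------------------------------------------
    def _time_weights(self, t):
        T = self.period
        nt = len(self.t)
        tau = np.mod(np.asarray(t, dtype=float) - self.t[0], T)
        pos = tau / T * nt
        i0 = np.floor(pos).astype(int) % nt
        frac = pos - np.floor(pos)
        return i0, (i0 + 1) % nt, frac

    def _space_weights(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nx, ny = len(self.x), len(self.y)
        if self.periodic_x:
            gx = np.mod(x - self.x[0], nx * self.dx) / self.dx
        else:
            gx = np.clip((x - self.x[0]) / self.dx, 0, nx - 1)
        gy = np.clip((y - self.y[0]) / self.dy, 0, ny - 1)
        i0 = np.floor(gx).astype(int)
        j0 = np.floor(gy).astype(int)
        fx = gx - i0
        fy = gy - j0
        i0 %= nx
        i1 = (i0 + 1) % nx
        j1 = np.minimum(j0 + 1, ny - 1)
        return i0, i1, fx, j0, j1, fy

    def _interp_slice(self, arr2d, sw):
        i0, i1, fx, j0, j1, fy = sw
        return ((1 - fy) * ((1 - fx) * arr2d[j0, i0] + fx * arr2d[j0, i1])
                + fy * ((1 - fx) * arr2d[j1, i0] + fx * arr2d[j1, i1]))

    def _interp(self, arr, x, y, t):
        k0, k1, ft = self._time_weights(t)
        sw = self._space_weights(x, y)
        if np.ndim(t) == 0:
            a = self._interp_slice(arr[int(k0)], sw)
            b = self._interp_slice(arr[int(k1)], sw)
            return (1 - ft) * a + ft * b
        # per-point times: gather the two bracketing slices pointwise
        i0, i1, fx, j0, j1, fy = sw
        out = 0.0
        for kk, wt in ((k0, 1 - ft), (k1, ft)):
            val = ((1 - fy) * ((1 - fx) * arr[kk, j0, i0] + fx * arr[kk, j0, i1])
                   + fy * ((1 - fx) * arr[kk, j1, i0] + fx * arr[kk, j1, i1]))
            out = out + wt * val
        return out

    def velocity(self, x, y, t):
        """Interpolated (u, v) at point(s) and time(s)."""
        return self._interp(self.u, x, y, t), self._interp(self.v, x, y, t)

    def gradient_grids(self):
        """Per-slice velocity-gradient grids (cached): du/dx, du/dy, dv/dx, dv/dy."""
        if "gradient_grids" not in self.attrs:
            from ._numerics import masked_gradient
            fl = self.fluid_mask
            g = [np.empty_like(self.u) for _ in range(4)]
            for k in range(len(self.t)):
                g[0][k] = masked_gradient(self.u[k], self.dx, 1, fl, self.periodic_x)
                g[1][k] = masked_gradient(self.u[k], self.dy, 0, fl, False)
                g[2][k] = masked_gradient(self.v[k], self.dx, 1, fl, self.periodic_x)
                g[3][k] = masked_gradient(self.v[k], self.dy, 0, fl, False)
            self.attrs["gradient_grids"] = tuple(g)
        return self.attrs["gradient_grids"]

    def gradients(self, x, y, t):
        g = self.gradient_grids()
        return tuple(self._interp(gi, x, y, t) for gi in g)

    def sample(self, x, y, t):
        return (*self.velocity(x, y, t), *self.gradients(x, y, t))

    def at_time(self, t):
        """Time-interpolated (u, v) slices at scalar time t."""
        k0, k1, ft = self._time_weights(float(t))
        u = (1 - ft) * self.u[int(k0)] + ft * self.u[int(k1)]
        v = (1 - ft) * self.v[int(k0)] + ft * self.v[int(k1)]
        return u, v


def _grid_from_provider(provider, dx, nt, domain_height, domain_length):
    """Sample a provider's streamfunction and central-difference it to (u, v).

    Deriving the gridded velocities from the discrete streamfunction makes the
    discrete central divergence identically zero at interior fluid nodes.
    """
    forcing = provider.forcing
    x = np.arange(0.0, domain_length - 0.5 * dx, dx)
    y = np.arange(0.0, domain_height + 0.5 * dx, dx)
    t = np.arange(nt) * (forcing.T / nt)
    ny, nx = len(y), len(x)
    y_ext = np.concatenate([[-dx], y, [y[-1] + dx]])
    X = x[None, :]
    Yx = y_ext[:, None]
    mask = provider.substrate.is_solid(np.broadcast_to(X, (ny, nx)),
                                       np.broadcast_to(y[:, None], (ny, nx)))
    u = np.empty((nt, ny, nx))
    v = np.empty((nt, ny, nx))
    for k, tk in enumerate(t):
        psi = provider.streamfunction(np.broadcast_to(X, (ny + 2, nx)),
                                      np.broadcast_to(Yx, (ny + 2, nx)), tk)
        u[k] = (psi[2:, :] - psi[:-2, :]) / (2.0 * dx)
        v[k] = -(np.roll(psi[1:-1, :], -1, axis=1)
                 - np.roll(psi[1:-1, :], 1, axis=1)) / (2.0 * dx)
        u[k][mask] = 0.0
        v[k][mask] = 0.0
    nu = provider.fluid.nu if hasattr(provider, "fluid") else None
    return VelocityField(x=x, y=y, t=t, u=u, v=v, solid_mask=mask,
                         forcing=forcing, substrate=provider.substrate,
                         nu=nu, provider="gridded")


def regrid_field(fld: VelocityField, dx: float) -> VelocityField:
    """Resample a gridded field onto a uniform grid of spacing ``dx``.

    Velocities are bilinearly interpolated; the solid mask is resampled
    conservatively (a target node is solid if any source solid node falls
    within its grid cell).
    """
    if dx <= 0:
        raise ValueError("target dx must be positive")
    if dx > (fld.x[-1] - fld.x[0]) or dx > (fld.y[-1] - fld.y[0]):
        raise ValueError("target dx exceeds the domain extent")
    x_new = np.arange(fld.x[0], fld.x[-1] + 0.5 * dx, dx)
    x_new = x_new[x_new <= fld.x[-1] + 1e-12]
    y_new = np.arange(fld.y[0], fld.y[-1] + 0.5 * dx, dx)
    y_new = y_new[y_new <= fld.y[-1] + 1e-12]
    XX, YY = np.meshgrid(x_new, y_new)
    sw = fld._space_weights(XX, YY)
    nt = len(fld.t)
    u = np.empty((nt, len(y_new), len(x_new)))
    v = np.empty_like(u)
    for k in range(nt):
        u[k] = fld._interp_slice(fld.u[k], sw)
        v[k] = fld._interp_slice(fld.v[k], sw)
    # conservative mask: bin source solid nodes into target cells
    sy, sx = np.nonzero(fld.solid_mask)
    mask = np.zeros((len(y_new), len(x_new)), dtype=bool)
    if len(sy):
        ci = np.clip(np.round((fld.x[sx] - x_new[0]) / dx).astype(int), 0, len(x_new) - 1)
        cj = np.clip(np.round((fld.y[sy] - y_new[0]) / dx).astype(int), 0, len(y_new) - 1)
        mask[cj, ci] = True
    u[:, mask] = 0.0
    v[:, mask] = 0.0
    return VelocityField(x=x_new, y=y_new, t=fld.t.copy(), u=u, v=v,
                         solid_mask=mask, forcing=fld.forcing,
                         substrate=fld.substrate, nu=fld.nu,
                         provider="gridded", periodic_x=False)


# ---------------------------------------------------------------------------
# tracer particles and synthetic imagery
# ---------------------------------------------------------------------------

@dataclass
class ParticleTracks:
    """Per-particle (t, x, y) sequences stored long-form in a DataFrame.

    Columns: particle, t [s], x [mm], y [mm].  ``origin`` records whether the
    tracks are synthetic ground truth or PTV detections.
    """

    data: "object"  # pandas.DataFrame
    origin: str = "synthetic"

    def __post_init__(self):
        need = {"particle", "t", "x", "y"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"tracks table needs columns {sorted(need)}")

    @property
    def n_particles(self) -> int:
        return int(self.data["particle"].nunique())

    def positions_at(self, frame_times, atol=1e-6):
        """Dict frame_index -> (ids, x, y) for particles present at each time."""
        out = {}
        t = self.data["t"].to_numpy()
        for k, tf in enumerate(frame_times):
            sel = np.abs(t - tf) < atol
            sub = self.data[sel]
            out[k] = (sub["particle"].to_numpy(), sub["x"].to_numpy(),
                      sub["y"].to_numpy())
        return out

    def to_csv(self, path):
        df = self.data.rename(columns={"x": "x_mm", "y": "y_mm"})
        df = df[["particle", "t", "x_mm", "y_mm"]]
        df.to_csv(path, index=False, header=["particle_id", "t", "x_mm", "y_mm"])

    @classmethod
    def from_csv(cls, path, origin="synthetic"):
        import pandas as pd
        df = pd.read_csv(path)
        df = df.rename(columns={"particle_id": "particle",
                                "x_mm": "x", "y_mm": "y"})
        return cls(data=df, origin=origin)


def advect_tracers(provider, n: int = 50, seed: int = 0, duration: float = 5.5,
                   dt: float = 0.01, positions0=None, save_every: int = 1,
                   margin: float = 0.2) -> ParticleTracks:
    """Advect passive tracers through a flow with a fixed-step 4th-order scheme.

    Tracers are passive (zero swim speed).  ``positions0`` may supply explicit
    (n, 2) seed positions; otherwise ``n`` tracers are seeded uniformly at
    random in the fluid, at least ``margin`` mm from solid surfaces, using the
    given ``seed``.  Reproducible: same inputs give identical tracks.
    """
    import pandas as pd
    if positions0 is None:
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(seed)
        sub = getattr(provider, "substrate", None)
        L = provider.domain_length
        H = provider.domain_height
        xs = np.empty(0)
        ys = np.empty(0)
        while len(xs) < n:
            cx = rng.uniform(0.0, L, size=4 * n)
            cy = rng.uniform(margin, H, size=4 * n)
            if sub is not None:
                ok = sub.distance_to_solid(cx, cy) > margin
            else:
                ok = np.ones(cx.shape, bool)
            xs = np.concatenate([xs, cx[ok]])
            ys = np.concatenate([ys, cy[ok]])
        x = xs[:n].copy()
        y = ys[:n].copy()
    else:
        positions0 = np.asarray(positions0, dtype=float)
        x = positions0[:, 0].copy()
        y = positions0[:, 1].copy()
        sub = getattr(provider, "substrate", None)
        if sub is not None and np.any(sub.is_solid(x, y)):
            raise ValueError("tracer seeded inside the solid mask")
        n = len(x)

    nsteps = int(round(duration / dt))
    rec_t, rec_x, rec_y = [np.zeros(n)], [x.copy()], [y.copy()]
    t = 0.0
    for step in range(1, nsteps + 1):
        x, y = rk4_step(lambda xx, yy, tt: provider.velocity(xx, yy, tt), x, y, t, dt)
        t = step * dt
        if step % save_every == 0:
            rec_t.append(np.full(n, t))
            rec_x.append(x.copy())
            rec_y.append(y.copy())
    nt = len(rec_t)
    df = pd.DataFrame({
        "particle": np.tile(np.arange(n), nt),
        "t": np.concatenate(rec_t),
        "x": np.concatenate(rec_x),
        "y": np.concatenate(rec_y),
    }).sort_values(["particle", "t"], ignore_index=True)
    return ParticleTracks(data=df, origin="synthetic")


@dataclass(frozen=True)
class RenderOptics:
    """Synthetic camera model for rendering tracer imagery."""

    pixel_size: float = 0.031  # mm per pixel
    fps: float = 90.0          # frames per second
    spot_sigma: float = 1.5    # Gaussian spot width [px]
    amplitude: float = 100.0   # peak spot intensity
    noise_level: float = 0.0   # additive noise mean (uniform on [0, 2*level])
    shape: Optional[tuple] = None  # (rows, cols); derived from tracks if None

    def __post_init__(self):
        if self.pixel_size <= 0 or self.fps <= 0:
            raise ValueError("pixel_size and fps must be positive")


@dataclass
class FrameStack:
    """Stack of synthetic (or recorded) PTV frames: (frame, row, col)."""

    frames: np.ndarray
    pixel_size: float = 0.031
    fps: float = 90.0

    def __post_init__(self):
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frame stack needs >= 2 frames of 2D images")
        if self.pixel_size <= 0 or self.fps <= 0:
            raise ValueError("pixel_size and fps must be positive")

    def to_tiff(self, path):
        import tifffile
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         metadata={"pixel_size_mm": self.pixel_size,
                                   "fps": self.fps})

    @classmethod
    def from_tiff(cls, path, pixel_size=0.031, fps=90.0):
        import tifffile
        return cls(frames=np.asarray(tifffile.imread(path), dtype=float),
                   pixel_size=pixel_size, fps=fps)


def render_frames(tracks: ParticleTracks, optics: RenderOptics = RenderOptics(),
                  seed: int = 0) -> FrameStack:
    """Render particle tracks into a synthetic image stack.

    Each particle becomes a Gaussian spot at its per-frame position; uniform
    additive noise with mean ``noise_level`` is added.  The track sampling
    interval must equal 1/fps (within 1e-6 s).
    """
    df = tracks.data
    times = np.unique(df["t"].to_numpy())
    if len(times) < 2:
        raise ValueError("tracks must span at least 2 frames")
    dt = np.diff(times)
    if not np.allclose(dt, 1.0 / optics.fps, atol=1e-6):
        raise ValueError(
            f"track sampling ({np.median(dt):.5f} s) inconsistent with "
            f"fps = {optics.fps}")
    px = optics.pixel_size
    if optics.shape is None:
        rows = int(np.ceil(df["y"].max() / px)) + 8
        cols = int(np.ceil(df["x"].max() / px)) + 8
    else:
        rows, cols = optics.shape
    rng = np.random.default_rng(seed)
    nf = len(times)
    frames = np.zeros((nf, rows, cols), dtype=float)
    half = int(np.ceil(4 * optics.spot_sigma))
    stamp_idx = np.arange(-half, half + 1)
    by_time = {tf: k for k, tf in enumerate(times)}
    for tf, sub in df.groupby("t"):
        k = by_time[tf]
        for cx, cy in zip(sub["x"].to_numpy() / px, sub["y"].to_numpy() / px):
            r0, c0 = int(round(cy)), int(round(cx))
            rr = r0 + stamp_idx
            cc = c0 + stamp_idx
            rok = (rr >= 0) & (rr < rows)
            cok = (cc >= 0) & (cc < cols)
            if not (rok.any() and cok.any()):
                continue
            gy = np.exp(-0.5 * ((rr[rok] - cy) / optics.spot_sigma) ** 2)
            gx = np.exp(-0.5 * ((cc[cok] - cx) / optics.spot_sigma) ** 2)
            frames[k][np.ix_(rr[rok], cc[cok])] += optics.amplitude * np.outer(gy, gx)
    if optics.noise_level > 0:
        frames += rng.uniform(0.0, 2.0 * optics.noise_level, size=frames.shape)
    return FrameStack(frames=frames, pixel_size=px, fps=optics.fps)


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------

_REQUIRED_DATASETS = ("x", "y", "t", "u", "v", "solid_mask")


def write_field(fld: VelocityField, path) -> None:
    """Write a gridded field to an HDF5 archive (datasets /x /y /t /u /v
    /solid_mask, attributes dx, T, U0, nu, substrate JSON)."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=fld.x)
        f.create_dataset("y", data=fld.y)
        f.create_dataset("t", data=fld.t)
        f.create_dataset("u", data=fld.u)
        f.create_dataset("v", data=fld.v)
        f.create_dataset("solid_mask", data=fld.solid_mask.astype(np.uint8))
        f.attrs["dx"] = fld.dx
        f.attrs["periodic_x"] = fld.periodic_x
        if fld.forcing is not None:
            f.attrs["T"] = fld.forcing.T
            f.attrs["U0"] = fld.forcing.U0
            f.attrs["phase0"] = fld.forcing.phase0
        if fld.nu is not None:
            f.attrs["nu"] = fld.nu
        if fld.substrate is not None:
            f.attrs["substrate"] = fld.substrate.to_json()


def read_field(path) -> VelocityField:
    """Read a field archive written by :func:`write_field` (or hand-built to
    the same schema).  Raises ``ValueError`` naming any missing dataset."""
    import h5py
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise ValueError(f"field archive is missing dataset '/{name}'")
        x = f["x"][...].astype(float)
        y = f["y"][...].astype(float)
        t = f["t"][...].astype(float)
        u = f["u"][...].astype(float)
        v = f["v"][...].astype(float)
        mask = f["solid_mask"][...].astype(bool)
        if u.shape != (len(t), len(y), len(x)) or v.shape != u.shape:
            raise ValueError(
                f"inconsistent shapes in archive: u{u.shape}, v{v.shape}, "
                f"expected {(len(t), len(y), len(x))}")
        if mask.shape != u.shape[1:]:
            raise ValueError("inconsistent solid_mask shape in archive")
        forcing = None
        if "T" in f.attrs and "U0" in f.attrs:
            forcing = OscillatoryForcing(U0=float(f.attrs["U0"]),
                                         T=float(f.attrs["T"]),
                                         phase0=float(f.attrs.get("phase0", 0.0)))
        substrate = None
        if "substrate" in f.attrs:
            substrate = SubstrateProfile.from_json(str(f.attrs["substrate"]))
        nu = float(f.attrs["nu"]) if "nu" in f.attrs else None
        periodic_x = bool(f.attrs.get("periodic_x", True))
    return VelocityField(x=x, y=y, t=t, u=u, v=v, solid_mask=mask,
                         forcing=forcing, substrate=substrate, nu=nu,
                         provider="gridded", periodic_x=periodic_x)


def export_slice_csv(fld: VelocityField, t: float, path) -> None:
    """Export a single time slice in long format: t, x, y, u, v."""
    import pandas as pd
    u, v = fld.at_time(t)
    XX, YY = np.meshgrid(fld.x, fld.y)
    pd.DataFrame({"t": t, "x": XX.ravel(), "y": YY.ravel(),
                  "u": u.ravel(), "v": v.ravel()}).to_csv(path, index=False)
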