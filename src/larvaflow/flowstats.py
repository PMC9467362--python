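"""Quantitative flow analysis: velocity gradients, Q-criterion vortex
identification, near-substrate band speeds, settling windows, and the
turbulence energy fraction.

The Q-criterion Q = 1/2 (|Omega|^2 - |S|^2) (Frobenius norms of the vorticity
and rate-of-strain tensors) is positive where local rotation exceeds local
strain -- a signature of true recirculation, as opposed to parallel shear.
Because measured fields are noisy near surfaces, vortex regions are defined as
connected components of Q > Q_thresh, where Q_thresh is the standard deviation
of Q over all fluid nodes and time slices of one period.

Settling windows are the intervals during which the mean flow speed within a
near-substrate band (default 1.5 mm, roughly 3-5 larval body lengths) drops
below the larval swimming speed plus one standard deviation (default
3 + 1 = 4 mm/s), so that larvae can actively reach and attach to the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._numerics import below_threshold_intervals, masked_gradient
from .flowfield import VelocityField

__all__ = [
    "GradientField",
    "QField",
    "SettlingWindows",
    "velocity_gradients",
    "q_criterion",
    "q_threshold",
    "q_field",
    "vortex_regions",
    "band_speed",
    "settling_windows",
    "classify_points_by_q",
    "turbulent_energy_fraction",
]


@dataclass
class GradientField:
    """Velocity-gradient components on the grid [1/s], with tensor parts."""

    dudx: np.ndarray
    dudy: np.ndarray
    dvdx: np.ndarray
    dvdy: np.ndarray
    fluid_mask: Optional[np.ndarray] = None

    @property
    def omega_z(self) -> np.ndarray:
        """Scalar vorticity dv/dx - du/dy."""
        return self.dvdx - self.dudy

    @property
    def s_xy(self) -> np.ndarray:
        """Off-diagonal rate-of-strain component 1/2 (du/dy + dv/dx)."""
        return 0.5 * (self.dudy + self.dvdx)

    def omega_tensor(self):
        """Antisymmetric vorticity tensor 1/2 (grad U - grad U^T), shape (..., 2, 2)."""
        o12 = 0.5 * (self.dudy - self.dvdx)
        z = np.zeros_like(o12)
        return np.stack([np.stack([z, o12], -1),
                         np.stack([-o12, z], -1)], -2)

    def strain_tensor(self):
        """Symmetric rate-of-strain tensor 1/2 (grad U + grad U^T)."""
        sxy = self.s_xy
        return np.stack([np.stack([self.dudx, sxy], -1),
                         np.stack([sxy, self.dvdy], -1)], -2)


def velocity_gradients(fld: VelocityField, t: Optional[float] = None,
                       t_index: Optional[int] = None) -> GradientField:
    """Velocity gradients of one time slice by masked finite differences.

    Central second-order differences on the uniform grid; one-sided
    second-order stencils adjacent to the solid mask and domain edges
    (gradients are never computed across solid nodes).
    """
    fl = fld.fluid_mask
    for axis, n in ((0, fl.shape[0]), (1, fl.shape[1])):
        if fl.any(axis=axis).sum() < 3 and n < 3:
            raise ValueError("grid needs >= 3 fluid nodes along each axis")
    if t_index is not None:
        u, v = fld.u[t_index], fld.v[t_index]
    elif t is not None:
        u, v = fld.at_time(t)
    else:
        raise ValueError("provide t or t_index")
    per = fld.periodic_x
    return GradientField(
        dudx=masked_gradient(u, fld.dx, 1, fl, per),
        dudy=masked_gradient(u, fld.dy, 0, fl, False),
        dvdx=masked_gradient(v, fld.dx, 1, fl, per),
        dvdy=masked_gradient(v, fld.dy, 0, fl, False),
        fluid_mask=fl,
    )


def q_criterion(grad: GradientField) -> np.ndarray:
    """Q = 1/2 (|Omega|^2 - |S|^2) with Frobenius norms [1/s^2].

    For 2D divergence-free fields this equals det(grad U); positive values
    mark rotation-dominated (recirculating) regions.
    """
    om = 0.5 * (grad.dudy - grad.dvdx)
    sxy = grad.s_xy
    norm_omega2 = 2.0 * om * om
    norm_s2 = grad.dudx ** 2 + grad.dvdy ** 2 + 2.0 * sxy * sxy
    return 0.5 * (norm_omega2 - norm_s2)


def q_threshold(q: np.ndarray, fluid_mask: Optional[np.ndarray] = None) -> float:
    """Vortex-identification threshold: population SD of Q over all fluid
    space-time samples of one period."""
    q = np.asarray(q, dtype=float)
    if fluid_mask is not None:
        mask = np.broadcast_to(fluid_mask, q.shape)
        samples = q[mask]
    else:
        samples = q.ravel()
    if samples.size == 0:
        raise ValueError("no fluid samples to threshold")
    return float(np.std(samples))


@dataclass
class QField:
    """Q-criterion history for one period of a gridded field."""

    q: np.ndarray                  # (nt, ny, nx) [1/s^2]
    q_thresh: float                # SD-based threshold [1/s^2]
    fluid_mask: np.ndarray
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray

    @property
    def max_q_map(self) -> np.ndarray:
        """Per-node maximum of Q over the period."""
        return self.q.max(axis=0)

    def labels(self, t_index: int, min_area: int = 4) -> np.ndarray:
        return vortex_regions(self.q[t_index], self.q_thresh, min_area)


def q_field(fld: VelocityField) -> QField:
    """Compute Q on every stored time slice and the SD threshold."""
    q = np.empty_like(fld.u)
    for k in range(len(fld.t)):
        q[k] = q_criterion(velocity_gradients(fld, t_index=k))
    thr = q_threshold(q, fld.fluid_mask)
    return QField(q=q, q_thresh=thr, fluid_mask=fld.fluid_mask,
                  x=fld.x, y=fld.y, t=fld.t)


def vortex_regions(q: np.ndarray, q_thresh: float, min_area: int = 4) -> np.ndarray:
    """Label connected vortex regions: 4-connected components of Q > Q_thresh,
    discarding components smaller than ``min_area`` cells.  Returns an integer
    label image (0 = background)."""
    above = np.asarray(q) > q_thresh
    labels, n = ndimage.label(above)  # default structure = 4-connectivity
    if n == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    # relabel consecutively
    out, _ = ndimage.label(labels > 0)
    return out


def _band_mask(fld: VelocityField, band_height: float, cavities_only: bool):
    sub = fld.substrate
    YY = fld.y[:, None]
    XX = fld.x[None, :]
    if sub is None:
        elev = np.zeros((1, len(fld.x)))
    else:
        elev = sub.elevation(fld.x)[None, :]
    band = (YY > elev) & (YY - elev <= band_height) & fld.fluid_mask
    if cavities_only:
        if sub is None or sub.kind != "ridged":
            raise ValueError("cavities_only requires a ridged substrate")
        xt = np.mod(XX, sub.period)
        band &= np.broadcast_to(xt > sub.ridge_width, band.shape)
    return band


def band_speed(fld: VelocityField, band_height: float = 1.5,
               cavities_only: bool = False) -> np.ndarray:
    """Mean speed |U| within the near-substrate band, per time slice [mm/s].

    The band follows the local surface: fluid nodes whose height above the
    local substrate elevation is in (0, band_height].  With
    ``cavities_only=True`` the band is restricted to the inter-ridge gaps.
    """
    if band_height <= 0:
        raise ValueError("band_height must be positive")
    band = _band_mask(fld, band_height, cavities_only)
    if not band.any():
        raise ValueError("near-substrate band contains no fluid nodes")
    speed = np.hypot(fld.u, fld.v)
    return speed[:, band].mean(axis=1)


@dataclass
class SettlingWindows:
    """Intervals during which the band speed is below the larval threshold."""

    intervals: list                # [(t_start, t_end)] within one period
    threshold: float               # [mm/s]
    band_height: float             # [mm]
    T: float                       # forcing period [s]

    @property
    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals])

    @property
    def count(self) -> int:
        return len(self.intervals)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum()) if self.intervals else 0.0

    @property
    def period_fraction(self) -> float:
        return min(self.total_duration / self.T, 1.0)

    def summary(self) -> dict:
        return {"count": self.count,
                "durations_s": self.durations.tolist(),
                "total_duration_s": self.total_duration,
                "period_fraction": self.period_fraction,
                "threshold_mm_s": self.threshold,
                "band_height_mm": self.band_height}


def settling_windows(times: Sequence[float], series: Sequence[float],
                     u_ell: float = 3.0, sd_u: float = 1.0,
                     T: Optional[float] = None,
                     threshold: Optional[float] = None,
                     band_height: float = 1.5) -> SettlingWindows:
    """Settling windows of a near-substrate band-speed series over one period.

    Maximal intervals where the series is below ``threshold`` (default
    u_l + 1 SD = 4 mm/s); window boundaries are located by linear
    interpolation and the series is treated as periodic, so a window spanning
    the period wrap counts once.
    """
    if threshold is None:
        threshold = u_ell + sd_u
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    times = np.asarray(times, dtype=float)
    if T is None:
        T = float(times[-1] - times[0])
    intervals = below_threshold_intervals(times, np.asarray(series, float),
                                          threshold, period=T)
    return SettlingWindows(intervals=intervals, threshold=float(threshold),
                           band_height=band_height, T=float(T))


def classify_points_by_q(points, qf: QField, column_height: float = 1.5):
    """For surface points, is any fluid node in the one-cell-wide column up to
    ``column_height`` above the point ever above Q_thresh during the period?

    Returns a boolean array, one entry per (x, y) point.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dx = qf.x[1] - qf.x[0] if len(qf.x) > 1 else np.inf
    out = np.zeros(len(points), dtype=bool)
    exceed = (qf.q > qf.q_thresh) & np.broadcast_to(qf.fluid_mask, qf.q.shape)
    exceed_any = exceed.any(axis=0)
    for i, (px, py) in enumerate(points):
        if px < qf.x[0] - dx / 2 or px > qf.x[-1] + dx / 2 \
                or py < qf.y[0] or py > qf.y[-1]:
            raise ValueError(f"point ({px}, {py}) outside the field domain")
        if column_height <= 0:
            continue
        col = np.abs(qf.x - px) <= dx / 2.0
        rows = (qf.y > py) & (qf.y <= py + column_height)
        out[i] = bool(exceed_any[np.ix_(rows, col)].any())
    return out


def turbulent_energy_fraction(series, dt: float, T: float) -> float:
    """Fraction of spectral power outside DC and the fundamental bin +/- 1.

    The series must uniformly sample at least 4 forcing periods.  For a pure
    sinusoid at 1/T the result is ~0; for sinusoid + white noise it
    approaches the noise share of the variance.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n * dt < 4.0 * T - 1e-9:
        raise ValueError("series must cover at least 4 periods")
    power = np.abs(np.fft.rfft(series)) ** 2
    k0 = int(round(n * dt / T))
    total = power[1:].sum()
    if total <= 1e-14 * power.sum():  # constant series up to roundoff
        return 0.0
    fundamental = power[max(k0 - 1, 1): k0 + 2].sum()
    return float((total - fundamental) / total)
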