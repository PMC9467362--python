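"""Low-level numerical helpers shared by the flow, analysis and simulation modules."""

from __future__ import annotations

import numpy as np

__all__ = ["smoothstep", "masked_gradient", "rk4_step", "below_threshold_intervals"]


def smoothstep(z: np.ndarray) -> np.ndarray:
    """C1 smoothstep: 0 for z <= 0, 1 for z >= 1, 3z^2 - 2z^3 between."""
    z = np.clip(z, 0.0, 1.0)
    return z * z * (3.0 - 2.0 * z)


def _shift(arr: np.ndarray, n: int, axis: int, periodic: bool, fill: float):
    """Return arr shifted so that result[i] = arr[i + n] along ``axis``."""
    if periodic:
        return np.roll(arr, -n, axis=axis)
    out = np.full_like(arr, fill)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if n >= 0:
        src[axis] = slice(n, None)
        dst[axis] = slice(None, arr.shape[axis] - n)
    else:
        src[axis] = slice(None, n)
        dst[axis] = slice(-n, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def masked_gradient(
    f: np.ndarray,
    spacing: float,
    axis: int,
    fluid: np.ndarray,
    periodic: bool = False,
) -> np.ndarray:
    """Finite-difference derivative of ``f`` that never differences across solid.

    Second-order central differences where both neighbours along ``axis`` are
    fluid, second-order one-sided stencils where only one side is available,
    first-order as a last resort, zero where a node is isolated.  Solid nodes
    get zero.  ``fluid`` is a boolean array of the same shape as ``f``.
    """
    h = float(spacing)
    fb = fluid.astype(bool)
    fp = _shift(f, 1, axis, periodic, 0.0)
    fm = _shift(f, -1, axis, periodic, 0.0)
    fpp = _shift(f, 2, axis, periodic, 0.0)
    fmm = _shift(f, -2, axis, periodic, 0.0)
    okp = _shift(fb, 1, axis, periodic, False)
    okm = _shift(fb, -1, axis, periodic, False)
    okpp = _shift(fb, 2, axis, periodic, False)
    okmm = _shift(fb, -2, axis, periodic, False)

    out = np.zeros_like(f, dtype=float)
    done = np.zeros_like(fb)

    sel = fb & okp & okm
    out[sel] = ((fp - fm) / (2.0 * h))[sel]
    done |= sel
    sel = fb & ~done & okp & okpp
    out[sel] = ((-3.0 * f + 4.0 * fp - fpp) / (2.0 * h))[sel]
    done |= sel
    sel = fb & ~done & okm & okmm
    out[sel] = ((3.0 * f - 4.0 * fm + fmm) / (2.0 * h))[sel]
    done |= sel
    sel = fb & ~done & okp
    out[sel] = ((fp - f) / h)[sel]
    done |= sel
    sel = fb & ~done & okm
    out[sel] = ((f - fm) / h)[sel]
    return out


def rk4_step(velocity, x, y, t, dt):
    """One classical Runge-Kutta step of dx/dt = u(x, y, t), dy/dt = v(x, y, t)."""
    k1x, k1y = velocity(x, y, t)
    k2x, k2y = velocity(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y, t + 0.5 * dt)
    k3x, k3y = velocity(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y, t + 0.5 * dt)
    k4x, k4y = velocity(x + dt * k3x, y + dt * k3y, t + dt)
    xn = x + dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
    yn = y + dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
    return xn, yn


def below_threshold_intervals(times, series, threshold, period=None):
    """Maximal intervals where ``series`` < ``threshold``, with sub-sample
    boundaries located by linear interpolation.

    If ``period`` is given the series is treated as one period of a periodic
    signal: an interval touching t = times[0] is merged with one touching
    times[0] + period.  Returns a list of (t_start, t_end).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if period is not None:
        times = np.append(times, times[0] + period)
        series = np.append(series, series[0])
    below = series < threshold
    if not below.any():
        return []
    if below.all():
        return [(times[0], times[-1])]

    intervals = []
    start = None
    for i in range(len(times)):
        if below[i] and start is None:
            if i == 0:
                start = times[0]
            else:  # crossing between i-1 and i
                f = (threshold - series[i - 1]) / (series[i] - series[i - 1])
                start = times[i - 1] + f * (times[i] - times[i - 1])
        elif not below[i] and start is not None:
            f = (threshold - series[i - 1]) / (series[i] - series[i - 1])
            intervals.append((start, times[i - 1] + f * (times[i] - times[i - 1])))
            start = None
    if start is not None:
        intervals.append((start, times[-1]))

    if period is not None and len(intervals) >= 2:
        t0, tN = times[0], times[-1]
        if intervals[0][0] <= t0 + 1e-12 and intervals[-1][1] >= tN - 1e-12:
            first = intervals.pop(0)
            last = intervals.pop()
            # wrap: shift the tail interval back by one period and merge
            intervals.append((last[0] - period, first[1]))
    return intervals
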