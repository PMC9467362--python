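"""Particle tracking velocimetry: detect tracer particles, link them into
tracks, and grid phase-averaged velocity fields.

The pipeline mirrors flume practice: fluorescent tracers are imaged at 90
frames/s and 31 um/px, detections are linked frame-to-frame by nearest
neighbour, per-link velocities are assigned to the midpoint of the link, and
fields are averaged over 40-frame phase windows (0.44 s at 90 fps).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage import measure

from .flowfield import FrameStack, OscillatoryForcing, ParticleTracks

__all__ = [
    "DetectionParams",
    "LinkingParams",
    "PhaseAveragedField",
    "detect_particles",
    "link_tracks",
    "grid_velocities",
    "phase_windows",
]


@dataclass(frozen=True)
class DetectionParams:
    """Particle detection settings (threshold as a fraction of the frame max)."""

    intensity_threshold: float = 0.5
    min_area: int = 2          # px
    connectivity: int = 2      # skimage convention: 2 = 8-connected

    def __post_init__(self):
        if not 0 < self.intensity_threshold < 1:
            raise ValueError("intensity_threshold must be in (0, 1)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


@dataclass(frozen=True)
class LinkingParams:
    """Frame-to-frame linking: greedy nearest neighbour within max_disp px."""

    max_disp: float = 5.0

    def __post_init__(self):
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")


def detect_particles(frame: np.ndarray,
                     params: DetectionParams = DetectionParams()) -> pd.DataFrame:
    """Intensity-weighted centroids of bright connected components.

    Returns a DataFrame with columns x, y (pixel coordinates, x = column,
    y = row) and intensity (component total).  An all-zero frame yields an
    empty table.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    peak = frame.max()
    if peak <= 0:
        return pd.DataFrame(columns=["x", "y", "intensity"])
    mask = frame > params.intensity_threshold * peak
    labels = measure.label(mask, connectivity=params.connectivity)
    rows = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < params.min_area:
            continue
        cy, cx = region.centroid_weighted
        rows.append((cx, cy, float(region.image_intensity.sum())))
    return pd.DataFrame(rows, columns=["x", "y", "intensity"])


def link_tracks(detections: Sequence[pd.DataFrame],
                params: LinkingParams = LinkingParams(),
                fps: float = 90.0, pixel_size: float = 0.031) -> ParticleTracks:
    """Link per-frame detections into tracks by greedy nearest neighbour.

    Candidate links between consecutive frames are assigned in order of
    ascending distance; links longer than ``max_disp`` px are forbidden, and
    unmatched detections start new tracks.  Positions are converted to mm
    via ``pixel_size`` and times to seconds via ``fps``.
    """
    if len(detections) < 2:
        raise ValueError("need detections from at least 2 frames")
    next_id = 0
    # current track id per detection of the previous frame
    prev = detections[0]
    prev_ids = list(range(len(prev)))
    next_id = len(prev)
    rows = []

    def emit(frame_idx, det, ids):
        for (x, y), pid in zip(det[["x", "y"]].to_numpy(), ids):
            rows.append((pid, frame_idx / fps, x * pixel_size, y * pixel_size))

    emit(0, prev, prev_ids)
    for k in range(1, len(detections)):
        cur = detections[k]
        cur_ids = [-1] * len(cur)
        if len(prev) and len(cur):
            d = cdist(prev[["x", "y"]].to_numpy(), cur[["x", "y"]].to_numpy())
            pairs = np.argwhere(d <= params.max_disp)
            order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
            used_prev = set()
            for i, j in pairs[order]:
                if i in used_prev or cur_ids[j] != -1:
                    continue
                used_prev.add(int(i))
                cur_ids[j] = prev_ids[i]
        for j in range(len(cur)):
            if cur_ids[j] == -1:
                cur_ids[j] = next_id
                next_id += 1
        emit(k, cur, cur_ids)
        prev, prev_ids = cur, cur_ids
    df = pd.DataFrame(rows, columns=["particle", "t", "x", "y"])
    df = df.sort_values(["particle", "t"], ignore_index=True)
    return ParticleTracks(data=df, origin="detected")


def phase_windows(forcing: OscillatoryForcing, fps: float = 90.0,
                  n_frames: int = 40) -> dict:
    """The two named phase windows of the oscillation, as (t_start, t_end).

    "peak" is centred on the free-stream extremum (t = T/4 for a sine with
    zero initial phase), "turning" on the flow reversal (t = T/2).  Each
    window spans ``n_frames`` at ``fps`` (0.44 s for the 40-frame default).
    """
    half = 0.5 * n_frames / fps
    t_peak = (np.pi / 2.0 - forcing.phase0) / forcing.omega
    t_turn = (np.pi - forcing.phase0) / forcing.omega
    return {"peak": (t_peak - half, t_peak + half),
            "turning": (t_turn - half, t_turn + half)}


@dataclass
class PhaseAveragedField:
    """Phase-averaged gridded velocities from PTV tracks.

    ``u``/``v`` have shape (n_windows, ny, nx); cells with no samples are NaN
    (missing, not zero).  ``counts`` stores per-cell sample counts.
    """

    x: np.ndarray
    y: np.ndarray
    windows: dict                  # name -> (t_start, t_end)
    u: np.ndarray
    v: np.ndarray
    counts: np.ndarray
    window_names: list = dc_field(default_factory=list)

    def window_index(self, name: str) -> int:
        return self.window_names.index(name)


def grid_velocities(tracks: ParticleTracks, windows: dict,
                    dx: float = 0.5,
                    bounds: Optional[tuple] = None,
                    period: Optional[float] = None) -> PhaseAveragedField:
    """Bin per-link finite-difference velocities into grid cells per window.

    Velocities are position differences between consecutive samples of a
    track divided by the time step, assigned at the link midpoint.  A link
    belongs to a window if its mid-time (mod ``period`` when given) falls
    inside the window.  Cell values are means; sample counts are retained and
    empty cells are NaN.
    """
    df = tracks.data.sort_values(["particle", "t"])
    g = df.groupby("particle")
    t = df["t"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    same = df["particle"].to_numpy()[1:] == df["particle"].to_numpy()[:-1]
    dt = np.diff(t)[same]
    mx = 0.5 * (x[1:] + x[:-1])[same]
    my = 0.5 * (y[1:] + y[:-1])[same]
    mt = 0.5 * (t[1:] + t[:-1])[same]
    vu = (np.diff(x)[same]) / dt
    vv = (np.diff(y)[same]) / dt

    if bounds is None:
        if len(mx):
            bounds = (x.min(), x.max(), y.min(), y.max())
        else:
            bounds = (0.0, dx, 0.0, dx)
    x0, x1, y0, y1 = bounds
    xg = np.arange(x0, x1 + 0.5 * dx, dx)
    yg = np.arange(y0, y1 + 0.5 * dx, dx)
    nx, ny = len(xg), len(yg)
    names = list(windows)
    nw = len(names)
    usum = np.zeros((nw, ny, nx))
    vsum = np.zeros((nw, ny, nx))
    cnt = np.zeros((nw, ny, nx), dtype=int)
    if len(mx):
        ci = np.clip(np.round((mx - x0) / dx).astype(int), 0, nx - 1)
        cj = np.clip(np.round((my - y0) / dx).astype(int), 0, ny - 1)
        for w, name in enumerate(names):
            ta, tb = windows[name]
            if period is not None:
                tau = np.mod(mt - ta, period)
                sel = tau <= (tb - ta)
            else:
                sel = (mt >= ta) & (mt <= tb)
            np.add.at(usum[w], (cj[sel], ci[sel]), vu[sel])
            np.add.at(vsum[w], (cj[sel], ci[sel]), vv[sel])
            np.add.at(cnt[w], (cj[sel], ci[sel]), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(cnt > 0, usum / np.maximum(cnt, 1), np.nan)
        v = np.where(cnt > 0, vsum / np.maximum(cnt, 1), np.nan)
    return PhaseAveragedField(x=xg, y=yg, windows=dict(windows), u=u, v=v,
                              counts=cnt, window_names=names)
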