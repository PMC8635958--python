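"""Observables computed from simulation output.

Centroid velocity (μm/min), chemotaxis index (windowed cosine between the
velocity direction and the direction to the source, in [−1, 1]), and the
coverage ratio η (fraction of an obstacle-enclosed region swept by the cell
footprint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

__all__ = [
    "MetricSeries",
    "centroid_velocity",
    "chemotaxis_index",
    "chemotaxis_index_displacement",
    "coverage_ratio",
]


@dataclass
class MetricSeries:
    t: np.ndarray
    value: np.ndarray
    window: float = 0.0

    def mean(self, t_min: float | None = None, t_max: float | None = None) -> float:
        sel = np.ones(len(self.t), dtype=bool)
        if t_min is not None:
            sel &= self.t >= t_min
        if t_max is not None:
            sel &= self.t <= t_max
        vals = self.value[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else float("nan")


def _check_time(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError("time axis must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("uniform sampling required")
    return float(dt[0])


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]
    return out


def _velocity(t: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Central-difference velocity, one-sided at the ends, (n, 2) μm/s."""
    dt = _check_time(t)
    v = np.gradient(xy, dt, axis=0)
    return v


def centroid_velocity(
    t: np.ndarray, xy: np.ndarray, window: float = 60.0
) -> MetricSeries:
    """Boxcar-smoothed centroid speed in μm/min."""
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dt = _check_time(t)
    v = _velocity(t, xy)
    speed = np.hypot(v[:, 0], v[:, 1]) * 60.0
    n = max(1, int(round(window / dt)))
    return MetricSeries(t=t, value=_boxcar(speed, n), window=window)


def chemotaxis_index(
    t: np.ndarray,
    xy: np.ndarray,
    source_position: np.ndarray,
    window: float = 60.0,
    speed_floor: float = 0.2,
) -> MetricSeries:
    """CI(t) = windowed mean cosine between the instantaneous velocity and
    the unit vector from the centroid to the source; +1 dead-on, −1 dead
    away.  Samples where the smoothed speed is below ``speed_floor``
    (μm/min) are reported as NaN (direction undefined)."""
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    dt = _check_time(t)
    n = max(1, int(round(window / dt)))
    if n < 1 or len(t) < 2:
        raise ValueError("evaluation window too short")
    v = _velocity(t, xy)
    speed = np.hypot(v[:, 0], v[:, 1])
    to_src = np.asarray(source_position, dtype=float) - xy
    dist = np.hypot(to_src[:, 0], to_src[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (v * to_src).sum(axis=1) / (speed * dist)
    cosang = np.where(speed > 0, cosang, np.nan)
    # windowed mean ignoring NaN samples
    ci = np.full(len(t), np.nan)
    ok = np.isfinite(cosang)
    csum = np.cumsum(np.where(ok, cosang, 0.0))
    ccnt = np.cumsum(ok.astype(int))
    half = n // 2
    for i in range(len(t)):
        lo, hi = max(0, i - half), min(len(t) - 1, i + half)
        cnt = ccnt[hi] - (ccnt[lo - 1] if lo else 0)
        if cnt:
            s = csum[hi] - (csum[lo - 1] if lo else 0)
            ci[i] = s / cnt
    smoothed_speed = _boxcar(speed * 60.0, n)
    ci[smoothed_speed < speed_floor] = np.nan
    return MetricSeries(t=t, value=np.clip(ci, -1.0, 1.0), window=window)


def chemotaxis_index_displacement(
    t: np.ndarray,
    xy: np.ndarray,
    source_position: np.ndarray,
    window: float = 60.0,
) -> MetricSeries:
    """Alternative CI: net displacement toward the source divided by path
    length, over a sliding window."""
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    dt = _check_time(t)
    n = max(2, int(round(window / dt)))
    steps = np.diff(xy, axis=0)
    path = np.hypot(steps[:, 0], steps[:, 1])
    cpath = np.concatenate([[0.0], np.cumsum(path)])
    ci = np.full(len(t), np.nan)
    src = np.asarray(source_position, dtype=float)
    for i in range(len(t)):
        lo, hi = max(0, i - n // 2), min(len(t) - 1, i + n // 2)
        plen = cpath[hi] - cpath[lo]
        if plen <= 0:
            continue
        disp = xy[hi] - xy[lo]
        u = src - xy[lo]
        u = u / np.hypot(*u)
        ci[i] = float(disp @ u) / plen
    return MetricSeries(t=t, value=np.clip(ci, -1.0, 1.0), window=window)


def coverage_ratio(
    times: np.ndarray,
    polygons: list,
    region_center: np.ndarray,
    region_radius: float,
    obstacles: list | None = None,
    pitch: float = 0.25,
) -> MetricSeries:
    """Coverage ratio η(t): fraction of the region (disk minus obstacle
    disks) swept by the union of cell footprints up to t.  Monotone
    non-decreasing by construction."""
    center = np.asarray(region_center, dtype=float)
    r = float(region_radius)
    ax = np.arange(center[0] - r, center[0] + r + pitch, pitch)
    ay = np.arange(center[1] - r, center[1] + r + pitch, pitch)
    gx, gy = np.meshgrid(ax, ay)
    pts = np.c_[gx.ravel(), gy.ravel()]
    d = pts - center
    in_region = np.hypot(d[:, 0], d[:, 1]) <= r
    for ob in obstacles or []:
        dd = pts - ob.center
        in_region &= np.hypot(dd[:, 0], dd[:, 1]) > ob.radius
    pts = pts[in_region]
    if len(pts) == 0:
        raise ValueError("empty coverage region")
    covered = np.zeros(len(pts), dtype=bool)
    eta = np.empty(len(times))
    for i, poly in enumerate(polygons):
        todo = ~covered
        if todo.any():
            covered[todo] = Path(poly).contains_points(pts[todo])
        eta[i] = covered.mean()
    return MetricSeries(t=np.asarray(times, dtype=float), value=eta)
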