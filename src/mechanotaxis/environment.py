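"""Chemoattractant field, obstacles and confinement.

The attractant comes from scheduled point sources with a steady far field
C(r) = C0·r0/max(r, r0) (an exponential decay is available as an option).
Gradient strength is parameterized the way chemotaxis assays report it: the
percentage concentration difference across one cell diameter, measured at
the cell.  Obstacles are rigid frictionless disks: any node that penetrates
one is projected back to its surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Source",
    "Obstacle",
    "Environment",
    "attractant_at",
    "gradient_percentage",
    "place_source_for_gradient",
    "project_out_of_obstacles",
    "obstacle_ring",
]

CONTACT_TOL = 0.05  # μm


@dataclass
class Source:
    """Chemoattractant point source.

    kind "inverse":  C(r) = C0·r0/max(r, r0)
    kind "exp":      C(r) = C0·exp(−(r − r0)/decay_length) for r > r0, else C0
    """

    position: np.ndarray
    onset: float = 0.0
    strength: float = 1.0
    core_radius: float = 1.0
    kind: str = "inverse"
    decay_length: float = 50.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.onset < 0:
            raise ValueError("onset time must be nonnegative")
        if self.kind not in ("inverse", "exp"):
            raise ValueError(f"unknown source kind {self.kind!r}")

    def concentration(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.kind == "inverse":
            return self.strength * self.core_radius / np.maximum(r, self.core_radius)
        return self.strength * np.exp(
            -np.maximum(r - self.core_radius, 0.0) / self.decay_length
        )


@dataclass
class Obstacle:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("obstacle radius must be positive")


@dataclass
class Environment:
    sources: list = field(default_factory=list)
    obstacles: list = field(default_factory=list)
    confinement_center: np.ndarray | None = None
    confinement_radius: float | None = None

    def active_sources(self, t: float):
        return [s for s in self.sources if t >= s.onset]

    def has_stimulus(self, t: float) -> bool:
        return bool(self.active_sources(t))

    def attractant(self, points: np.ndarray, t: float) -> np.ndarray:
        return attractant_at(points, t, self)

    def project(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return project_out_of_obstacles(positions, self)


def attractant_at(points: np.ndarray, t: float, env: Environment) -> np.ndarray:
    """Total attractant concentration at each point, summed over the sources
    active at time t (zero before every onset)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(pts))
    for s in env.active_sources(t):
        d = pts - s.position
        out += s.concentration(np.hypot(d[:, 0], d[:, 1]))
    return out


def project_out_of_obstacles(
    positions: np.ndarray, env: Environment
) -> tuple[np.ndarray, np.ndarray]:
    """Move any position strictly inside an obstacle to the nearest surface
    point, and clamp positions to the confinement disk if one is set.
    Returns (corrected positions, contact flags).  Idempotent."""
    pos = np.asarray(positions, dtype=float).copy()
    contact = np.zeros(len(pos), dtype=bool)
    for ob in env.obstacles:
        d = pos - ob.center
        r = np.hypot(d[:, 0], d[:, 1])
        degenerate = r < 1e-12
        if degenerate.any():
            # projection direction ambiguous at the center: push along +x
            d[degenerate] = (1.0, 0.0)
            r[degenerate] = 1.0
        inside = r < ob.radius
        if inside.any():
            pos[inside] = ob.center + ob.radius * d[inside] / r[inside, None]
        contact |= r < ob.radius + CONTACT_TOL
    if env.confinement_radius is not None:
        c = env.confinement_center if env.confinement_center is not None else np.zeros(2)
        d = pos - c
        r = np.hypot(d[:, 0], d[:, 1])
        out = r > env.confinement_radius
        if out.any():
            pos[out] = c + env.confinement_radius * d[out] / r[out, None]
        contact |= r > env.confinement_radius - CONTACT_TOL
    return pos, contact


def gradient_percentage(
    source: Source, centroid: np.ndarray, cell_diameter: float
) -> float:
    """Gradient strength in percent: 100·(C_front − C_back)/C_mid, where
    front/back sit on the cell circle along the source axis and C_mid is at
    the centroid."""
    centroid = np.asarray(centroid, dtype=float)
    d = float(np.hypot(*(source.position - centroid)))
    w = cell_diameter
    if d - w / 2.0 <= source.core_radius:
        raise ValueError("cell overlaps the source core")
    c_front = source.concentration(np.array([d - w / 2.0]))[0]
    c_back = source.concentration(np.array([d + w / 2.0]))[0]
    c_mid = source.concentration(np.array([d]))[0]
    return 100.0 * (c_front - c_back) / c_mid


def place_source_for_gradient(
    percent: float,
    direction: np.ndarray,
    centroid: np.ndarray,
    cell_diameter: float,
    onset: float = 0.0,
    concentration_at_cell: float = 1.0,
    kind: str = "inverse",
    core_radius: float = 1.0,
    decay_length: float = 50.0,
) -> Source:
    """Place a point source along ``direction`` from ``centroid`` so that the
    gradient strength at the cell equals ``percent``, with the strength
    normalized so the concentration at the centroid is
    ``concentration_at_cell``.

    For the 1/r field the distance has the closed form
    d = w (1 + sqrt(1 + a²)) / (2a), a = percent/100.  For the exponential
    field the percentage is independent of distance, so the decay length is
    solved instead (closed form with a bisection refinement) and the source
    is placed ten diameters away.
    """
    if percent <= 0:
        raise ValueError("percent must be positive")
    w = cell_diameter
    a = percent / 100.0
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.hypot(*direction)
    centroid = np.asarray(centroid, dtype=float)

    if kind == "inverse":
        d = w * (1.0 + np.sqrt(1.0 + a * a)) / (2.0 * a)
    else:
        d = 10.0 * w
        # p/100 = 2 sinh(w / 2λ): invert for λ, then polish by bisection
        decay_length = w / (2.0 * np.arcsinh(a / 2.0))
        probe = Source(position=centroid + d * direction, strength=1.0,
                       kind=kind, core_radius=core_radius,
                       decay_length=decay_length)

        def err(lam: float) -> float:
            probe.decay_length = lam
            return gradient_percentage(probe, centroid, w) - percent

        lo, hi = decay_length / 4.0, decay_length * 4.0
        decay_length = brentq(err, lo, hi, xtol=1e-9)

    src = Source(
        position=centroid + d * direction,
        onset=onset,
        strength=1.0,
        core_radius=core_radius,
        kind=kind,
        decay_length=decay_length,
    )
    c_mid = src.concentration(np.array([d]))[0]
    src.strength = concentration_at_cell / c_mid
    return src


def obstacle_ring(
    center: np.ndarray = (0.0, 0.0),
    n: int = 6,
    ring_radius: float = 20.0,
    obstacle_radius: float = 5.0,
    phase: float = 0.0,
) -> list[Obstacle]:
    """n equally spaced circular obstacles centered on a ring."""
    center = np.asarray(center, dtype=float)
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return [
        Obstacle(center=center + ring_radius * np.array([np.cos(a), np.sin(a)]),
                 radius=obstacle_radius)
        for a in ang
    ]
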