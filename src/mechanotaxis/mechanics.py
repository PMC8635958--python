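"""Overdamped particle-spring mechanics of the membrane and lamellipod.

Membrane nodes obey the force balance  μ v_i = F_elas + F_vis + F_pro +
F_cont + F_drag (+ area restoring), integrated by explicit Euler with a
per-step displacement cap.  Interior (lamellipod) nodes are quasi-static:
each sits at the arithmetic mean of its Delaunay neighbors, the zero-net
force condition of zero-rest-length springs, solved as a sparse linear
system with the membrane as Dirichlet boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .mesh import (CellMesh, GeometryCache, IntegrityError, compute_geometry,
                   shift_down, shift_up, unique_edges)

log = logging.getLogger(__name__)

__all__ = [
    "MechanicsParams",
    "membrane_passive_forces",
    "active_forces",
    "area_drag_forces",
    "step_membrane",
    "relax_interior",
    "hill",
]


@dataclass
class MechanicsParams:
    """Mechanical coefficients (nN, μm, s units).

    mu          substrate friction per node (nN·s/μm)
    k           membrane spring stiffness (nN/μm)
    eta_m       membrane dashpot viscosity (nN·s/μm)
    K_lam       lamellipodial spring stiffness (nN/μm, rest length zero);
                formal — interior nodes are relaxed quasi-statically, so the
                equilibrium is independent of its value
    f_pro_max   maximal protrusive force per node (nN)
    f_cont_max  maximal contractile force per node (nN)
    c_drag      membrane–lamellipod relative-velocity coupling (nN·s/μm)
    k_area      area-restoring modulus (nN/μm^3)
    rest_edge_length  membrane spring rest length (μm); None = use the
                cell's initial membrane spacing (stress-free start)
    dt_mech     mechanics time step (s)
    hill_half_pip3 / hill_half_pip2   half-saturation concentrations of the
                protrusion / contraction Hill response
    hill_exponent     Hill steepness h
    """

    mu: float = 1.0
    k: float = 3.0
    eta_m: float = 1.0
    K_lam: float = 1.0
    f_pro_max: float = 1.2
    f_cont_max: float = 0.3
    c_drag: float = 0.1
    k_area: float = 0.15
    rest_edge_length: float | None = 0.698
    dt_mech: float = 1.0
    hill_half_pip3: float = 3.3
    hill_half_pip2: float = 2.8
    hill_exponent: float = 6.0
    force_smooth_passes: int = 3
    k_perim: float = 10.0
    mech_substeps: int = 16    # explicit-Euler substeps per master dt
    f_rac_half: float = 0.0    # Rac level half-enabling protrusion (0 = off)
    f_rho_half: float = 0.0    # RhoA level half-enabling contraction (0 = off)

    def __post_init__(self) -> None:
        for name in ("mu", "k", "eta_m", "K_lam", "f_pro_max", "f_cont_max",
                     "c_drag", "k_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rest_edge_length is not None and self.rest_edge_length < 0:
            raise ValueError("rest_edge_length must be nonnegative")
        if self.dt_mech <= 0:
            raise ValueError("dt_mech must be positive")


def hill(c: np.ndarray, c_half: float, h: float) -> np.ndarray:
    """Saturating Hill response H(c) = (c/c_half)^h / (1 + (c/c_half)^h)."""
    x = (np.asarray(c, dtype=float) / c_half) ** h
    return x / (1.0 + x)


def _smooth_periodic(x: np.ndarray, passes: int) -> np.ndarray:
    """Periodic (1/4, 1/2, 1/4) smoothing, ``passes`` times."""
    for _ in range(passes):
        x = 0.5 * x + 0.25 * (shift_up(x) + shift_down(x))
    return x


def _edge_spring_forces(
    membrane: np.ndarray, coeff_per_edge: np.ndarray
) -> np.ndarray:
    """Forces from per-edge scalar tensions (positive = edge pulls its ends
    together), distributed to both end nodes.  Sums to zero by construction.
    """
    edge = shift_up(membrane) - membrane
    ln = np.hypot(edge[:, 0], edge[:, 1])
    if np.any(ln <= 0):
        raise IntegrityError("zero-length membrane edge")
    u = edge / ln[:, None]
    f_edge = coeff_per_edge[:, None] * u          # force on node i from edge i
    return f_edge - shift_down(f_edge)            # equal/opposite on node i+1


def membrane_passive_forces(
    mesh: CellMesh,
    prev_positions: np.ndarray,
    params: MechanicsParams,
    dt_prev: float | None = None,
) -> np.ndarray:
    """Spring + dashpot (Kelvin–Voigt) forces on membrane nodes, (Nm, 2).

    The elastic tension of edge e is k·(ℓ_e − ℓ0); the viscous tension is
    η·dℓ_e/dt with the elongation rate taken as a finite difference against
    ``prev_positions`` over ``dt_prev`` (the duration of the last move,
    defaulting to ``dt_mech``).
    """
    if dt_prev is None:
        dt_prev = params.dt_mech
    cur = mesh.membrane
    ln = mesh.segment_lengths
    d_prev = shift_up(prev_positions) - prev_positions
    ln_prev = np.hypot(d_prev[:, 0], d_prev[:, 1])
    tension = params.k * (ln - params.rest_edge_length)
    tension += params.eta_m * (ln - ln_prev) / dt_prev
    if params.k_perim > 0:
        p0 = len(ln) * params.rest_edge_length
        tension += params.k_perim * (ln.sum() / p0 - 1.0)
    return _edge_spring_forces(cur, tension)


def active_forces(
    mesh: CellMesh,
    pip3: np.ndarray,
    pip2: np.ndarray,
    params: MechanicsParams,
    geom: GeometryCache | None = None,
    rac: np.ndarray | None = None,
    rho: np.ndarray | None = None,
) -> np.ndarray:
    """Protrusive (PIP3, outward) and contractile (PIP2, inward) forces.

    Forces act only where the species exceeds its spatial mean, i.e. on the
    polarized part of the membrane, with saturating Hill magnitude.
    Protrusion additionally requires local active Rac (actin polymerization
    is Rac-driven) and contraction active RhoA, through an ultrasensitive
    activation G²/(G½² + G²) — this is how the FilGAP brake stalls an
    over-strained front.  The force profile is smoothed over neighboring
    nodes (a pseudopod has finite width), which keeps protrusion coherent
    instead of node-by-node ruffling.
    """
    pip3 = np.asarray(pip3, float)
    pip2 = np.asarray(pip2, float)
    if np.any(pip3 < 0) or np.any(pip2 < 0):
        raise IntegrityError("negative phosphoinositide concentration")
    if geom is None:
        geom = compute_geometry(mesh)
    n = geom.normals
    h = params.hill_exponent
    pro = params.f_pro_max * hill(pip3, params.hill_half_pip3, h)
    con = params.f_cont_max * hill(pip2, params.hill_half_pip2, h)
    if rac is not None and params.f_rac_half > 0:
        r = np.asarray(rac, float)
        pro = pro * r * r / (params.f_rac_half ** 2 + r * r)
    if rho is not None and params.f_rho_half > 0:
        p = np.asarray(rho, float)
        con = con * p * p / (params.f_rho_half ** 2 + p * p)
    # polarity-relative gating: force only where the species exceeds its
    # spatial mean, ramping up linearly over the first 10% of excess.  The
    # continuous ramp (rather than a hard step) keeps float-epsilon spread
    # in a uniform field from switching on finite forces.
    with np.errstate(invalid="ignore"):
        gate3 = np.clip((pip3 / max(pip3.mean(), 1e-300) - 1.0) / 0.1, 0.0, 1.0)
        gate2 = np.clip((pip2 / max(pip2.mean(), 1e-300) - 1.0) / 0.1, 0.0, 1.0)
    pro = pro * gate3
    con = con * gate2
    pro = _smooth_periodic(pro, params.force_smooth_passes)
    con = _smooth_periodic(con, params.force_smooth_passes)
    return (pro - con)[:, None] * n


def area_drag_forces(
    mesh: CellMesh,
    v_membrane: np.ndarray,
    v_interior: np.ndarray,
    area_target: float,
    params: MechanicsParams,
    geom: GeometryCache | None = None,
    nearest: np.ndarray | None = None,
) -> np.ndarray:
    """Area-restoring force plus membrane–lamellipod drag, (Nm, 2).

    The area term is a uniform pressure p = k_area (A_target − A) applied on
    the edges (force p·ℓ_e·n̂_e per edge, split between its end nodes), so
    the pressure force sums to exactly zero over the closed contour — like
    real pressure, it can reshape the cell but never translate it.  F_drag
    couples each membrane node to the velocity of its nearest interior node
    (the index map can be precomputed and passed as ``nearest``).
    """
    if geom is None:
        geom = compute_geometry(mesh, with_angles=False)
    pressure = params.k_area * (area_target - geom.area)
    edge = shift_up(mesh.membrane) - mesh.membrane
    # outward edge normal times edge length: rotate the edge vector by -90°
    en = np.c_[edge[:, 1], -edge[:, 0]]
    f_edge = 0.5 * pressure * en
    f = f_edge + shift_down(f_edge)
    if params.c_drag > 0:
        if nearest is None:
            nearest = cKDTree(mesh.interior).query(mesh.membrane)[1]
        f = f - params.c_drag * (v_membrane - v_interior[nearest])
    return f


def step_membrane(
    mesh: CellMesh,
    total_forces: np.ndarray,
    env,
    params: MechanicsParams,
    dt: float | None = None,
) -> tuple[np.ndarray, float]:
    """Advance membrane positions by explicit Euler, v = F/μ.

    If the largest displacement exceeds 0.2 membrane spacings the time step
    is halved (as often as needed) and only the shortened step is taken; the
    caller is told how much time was consumed so it can re-evaluate forces
    and continue.  Obstacle/confinement projection is applied afterwards.

    Returns (new membrane positions, dt actually used).
    """
    if dt is None:
        dt = params.dt_mech
    v = total_forces / params.mu
    speed = np.hypot(v[:, 0], v[:, 1]).max()
    cap = 0.2 * mesh.segment_lengths.mean()
    dt_eff = dt
    halvings = 0
    while speed * dt_eff > cap and halvings < 30:
        dt_eff *= 0.5
        halvings += 1
    if halvings:
        log.debug("displacement cap hit: dt %.3g -> %.3g", dt, dt_eff)
    new = mesh.membrane + v * dt_eff
    if env is not None:
        new, _ = env.project(new)
    return new, dt_eff


def _interior_system(mesh: CellMesh):
    nb = mesh.n_membrane
    n = nb + mesh.n_interior
    tri = (mesh.full_triangles if mesh.full_triangles is not None
           else mesh.triangles)
    e = unique_edges(tri)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.ones(len(rows))
    A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg[nb:] == 0):
        raise IntegrityError("disconnected interior node in triangulation")
    Aii = A[nb:, nb:]
    L = sp.diags(deg[nb:]) - Aii
    rhs = A[nb:, :nb] @ mesh.membrane
    return L.tocsr(), rhs, deg[nb:]


def relax_interior(
    mesh: CellMesh, x0: np.ndarray | None = None, tol: float = 1e-10
) -> np.ndarray:
    """Quasi-static interior positions: each node at the mean of its
    Delaunay neighbors (zero net force of zero-rest-length springs), with
    the membrane as fixed boundary, solved as a sparse SPD linear system.

    If ``x0`` already satisfies the system (e.g. a repeated call) it is
    returned immediately.  The residual max |Σ_j (X_j − X_i)| is guaranteed
    below 1e-8 μm.
    """
    L, rhs, deg = _interior_system(mesh)
    if x0 is not None and np.abs(L @ x0 - rhs).max() < 1e-9:
        return np.asarray(x0, dtype=float).copy()
    try:
        lu = spla.splu(L.tocsc())
    except RuntimeError as exc:  # pragma: no cover - singular system
        raise IntegrityError(f"singular interior system: {exc}") from exc
    out = lu.solve(rhs)
    resid = np.abs(L @ out - rhs).max()
    if resid > 1e-8:
        raise IntegrityError(f"interior relaxation residual {resid:.3g} μm")
    return out
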