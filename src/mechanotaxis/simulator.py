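"""Master loop coupling mechanics, signaling and mechanosensing, plus the
four experiment protocols (spontaneous migration, gradient, mutant sweep,
obstacle ring).

One master step of length dt:

1. sample the attractant at the membrane nodes (GPCR layer runs only while
   a stimulus is scheduled);
2. signaling: GPCR → Rac/RhoA (with the FilGAP antagonism term) → PI layer;
3. mechanosensing: angular strain → bandpass-gated FilGAP release/return;
4. mechanics: passive + active + area/drag forces → membrane move (with the
   displacement cap, re-evaluating forces if the step was shortened) →
   obstacle projection;
5. dilution bookkeeping (amounts fixed, arc lengths updated);
6. quasi-static interior relaxation;
7. retriangulation with crosslink bookkeeping transfer.

All randomness flows from three independent streams (activation noise,
Monte-Carlo translocation, mesh jitter) spawned from the master seed, so a
run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import mechanics as mech
from . import mechanosensing as ms
from . import signaling as sig
from .config import SimConfig, apply_overrides
from .environment import Environment, place_source_for_gradient
from .mesh import (CellMesh, angle_strain, build_disk_mesh, compute_geometry,
                   polygon_centroid, retriangulate)
from .metrics import MetricSeries, centroid_velocity, chemotaxis_index

__all__ = ["Simulation", "SimulationOutput", "run_experiment", "PROTOCOLS"]

PROTOCOLS = ("random_migration", "gradient", "mutant_sweep", "obstacle_ring")


@dataclass
class SimulationOutput:
    """Time series and snapshots produced by one run."""

    t: np.ndarray                      # scalar-series times, s
    centroid: np.ndarray               # (n, 2) μm
    filgap_c: np.ndarray               # cytosolic FilGAP, μM
    bound_filgap: np.ndarray           # Σ m, molecules
    frac_fast: np.ndarray              # fraction of corners in fast release
    kymo_times: np.ndarray
    kymographs: dict                   # species -> (nt, Nm) concentrations
    snapshot_times: np.ndarray
    snapshots: list                    # membrane polygons, (Nm, 2) each
    source_position: np.ndarray | None
    totals_start: dict
    totals_end: dict
    config: dict
    master_seed: int

    def speed(self, window: float = 60.0) -> MetricSeries:
        return centroid_velocity(self.t, self.centroid, window)

    def ci(self, window: float = 60.0) -> MetricSeries:
        if self.source_position is None:
            raise ValueError("run had no attractant source")
        return chemotaxis_index(self.t, self.centroid, self.source_position,
                                window)


class Simulation:
    """Mutable simulation state advancing by master steps."""

    def __init__(self, config: SimConfig, master_seed: int | None = None,
                 environment: Environment | None = None):
        self.config = config
        self.master_seed = (config.master_seed if master_seed is None
                            else int(master_seed))
        seq = np.random.SeedSequence([self.master_seed & 0x7FFFFFFF, 17])
        s_noise, s_mc, s_mesh = seq.spawn(3)
        self.rng_noise = np.random.default_rng(s_noise)
        self.rng_mc = np.random.default_rng(s_mc)
        mesh_seed = int(np.random.default_rng(s_mesh).integers(0, 2**31 - 1))

        self.env = environment if environment is not None else Environment()
        self.mesh = build_disk_mesh(
            config.mesh.diameter, config.mesh.n_membrane,
            config.mesh.n_interior, seed=mesh_seed)
        # settle the lamellipod to its quasi-static equilibrium before
        # capturing reference angles, so the run starts strain-free
        for _ in range(200):
            new_int = mech.relax_interior(self.mesh, x0=self.mesh.interior)
            shift = float(np.abs(new_int - self.mesh.interior).max())
            self.mesh = dataclasses.replace(self.mesh, interior=new_int)
            self.mesh = retriangulate(self.mesh)
            if shift < 1e-9:
                break
        self.mesh.reference_angles = self.mesh.corner_angles.copy()
        geom = compute_geometry(self.mesh)
        self.area_target = geom.area
        if config.mechanics.rest_edge_length is None:
            config.mechanics.rest_edge_length = float(
                geom.segment_lengths.mean())
        self.state, self.cytosol = sig.make_uniform_state(
            self.mesh.node_arc_lengths, config.signaling)
        self.crosslinks, self.filgap_c = ms.init_crosslinks(
            self.mesh, config.mechano)
        self.prev_membrane = self.mesh.membrane.copy()
        self.prev_dt = config.mechanics.dt_mech
        self.v_membrane = np.zeros_like(self.mesh.membrane)
        self.v_interior = np.zeros_like(self.mesh.interior)
        self.t = 0.0
        self.stochastic = config.signaling.sigma_noise > 0

    # -- conserved totals ----------------------------------------------------

    def totals(self) -> dict:
        st, cy = self.state, self.cytosol
        return {
            "rac": float(st.rac.sum()) + cy.rac_i_amt,
            "rho": float(st.rho.sum()) + cy.rho_i_amt,
            "pi": float(st.pip3.sum() + st.pip2.sum()),
            "pi3k": float(st.n_pi3k.sum()) + float(cy.pi3k_free),
            "pten": float(st.n_pten.sum()) + float(cy.pten_free),
            "filgap": float(self.crosslinks.m.sum())
                      + self.filgap_c * ms.FILGAP_COUNTS_PER_UM,
        }

    # -- one master step -----------------------------------------------------

    def step(self) -> None:
        cfg = self.config
        dt = cfg.mechanics.dt_mech
        state, cyt = self.state, self.cytosol

        # (1) environment sampling + GPCR layer (only while stimulated)
        if self.env.has_stimulus(self.t):
            stimulus = self.env.attractant(self.mesh.membrane, self.t)
            state.s = stimulus
            sig.gpcr_step(state, cyt, stimulus, cfg.signaling, dt)
        else:
            state.s = np.zeros(self.mesh.n_membrane)

        # (2) Rac/RhoA with FilGAP antagonism, then the PI layer
        q_r, q_rho = sig.filgap_antagonism(
            self.filgap_c, state.conc("pip3"), cfg.signaling)
        sig.rac_rho_step(state, cyt, q_r, q_rho, cfg.signaling, dt,
                         self.rng_noise)
        sig.pi_step(state, cyt, cfg.signaling, dt, self.rng_mc,
                    stochastic=self.stochastic)

        # (3) strain-gated FilGAP exchange
        sng = ms.classify_strain(angle_strain(self.mesh),
                                 cfg.mechano.beta1, cfg.mechano.beta2)
        self.filgap_c = ms.filgap_step(
            self.crosslinks, self.filgap_c, sng, cfg.mechano, dt)

        # (4) mechanics, re-evaluating forces if the displacement cap bites
        # force-generating fields are per-node amounts on a reference arc
        # scale (the molecules available to the local actin machinery), so
        # pure mechanical compression cannot bootstrap a contraction front
        arc_ref = float(state.arc.mean())
        pip3c = state.pip3 / arc_ref
        pip2c = state.pip2 / arc_ref
        racc = state.conc("rac")
        rhoc = state.conc("rho")
        if cfg.mechanics.c_drag > 0:
            nearest = cKDTree(self.mesh.interior).query(self.mesh.membrane)[1]
        else:
            nearest = None
        # the dashpot rate is referenced to the membrane at the start of the
        # master step over the full dt (a stable finite difference even when
        # the displacement cap shortens individual sub-moves)
        start_membrane = self.mesh.membrane
        n_sub = max(1, cfg.mechanics.mech_substeps)
        t_used = 0.0
        for _ in range(4 * n_sub):
            remaining = dt - t_used
            if remaining <= 1e-12:
                break
            geom = compute_geometry(self.mesh, with_angles=False)
            forces = (
                mech.membrane_passive_forces(
                    self.mesh, self.prev_membrane, cfg.mechanics, dt_prev=dt)
                + mech.active_forces(self.mesh, pip3c, pip2c, cfg.mechanics,
                                     geom, rac=racc, rho=rhoc)
                + mech.area_drag_forces(self.mesh, self.v_membrane,
                                        self.v_interior, self.area_target,
                                        cfg.mechanics, geom, nearest=nearest)
            )
            new_mem, used = mech.step_membrane(
                self.mesh, forces, self.env, cfg.mechanics,
                dt=min(remaining, dt / n_sub))
            self.v_membrane = (new_mem - self.mesh.membrane) / used
            self.mesh = dataclasses.replace(self.mesh, membrane=new_mem)
            t_used += used
        self.prev_membrane = start_membrane

        # (5) dilution bookkeeping on the stretched/compressed lattice
        sig.rescale_amounts(state, self.mesh.node_arc_lengths)

        # (6) quasi-static lamellipod
        new_int = mech.relax_interior(self.mesh, x0=self.mesh.interior)
        self.v_interior = (new_int - self.mesh.interior) / dt
        self.mesh = dataclasses.replace(self.mesh, interior=new_int)

        # (7) retriangulate + crosslink transfer; the FLNa reference
        # configuration remodels slowly toward the current geometry so the
        # strain of a cell that stops deforming decays away
        self.mesh = retriangulate(self.mesh)
        self.crosslinks, self.filgap_c = ms.rebind_capacity(
            self.crosslinks, self.mesh, self.filgap_c)
        tau = cfg.mechano.tau_ref
        if tau > 0:
            lam = min(dt / tau, 1.0)
            self.mesh.reference_angles += lam * (
                self.mesh.corner_angles - self.mesh.reference_angles)

        self.t += dt

    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.mesh.membrane)

    # -- full run with recording ----------------------------------------------

    def run(self, t_end: float) -> SimulationOutput:
        cfg = self.config
        sch = cfg.schedule
        dt = cfg.mechanics.dt_mech
        totals_start = self.totals()

        times, cents, fils, bounds, fracs = [], [], [], [], []
        kymo_t, kymo = [], {k: [] for k in
                            ("pip3", "pip2", "rac", "rho", "a_act", "b_m")}
        snap_t, snaps = [], []

        def record(t):
            times.append(t)
            cents.append(self.centroid())
            fils.append(self.filgap_c)
            bounds.append(self.crosslinks.total_bound())
            sng = ms.classify_strain(angle_strain(self.mesh),
                                     cfg.mechano.beta1, cfg.mechano.beta2)
            fracs.append(float(sng.mean()) if sng.size else 0.0)

        next_rec = self.t
        next_kymo = self.t
        next_snap = self.t
        while self.t < t_end - 1e-9:
            if self.t >= next_rec - 1e-9:
                record(self.t)
                next_rec += sch.record_every
            if self.t >= next_kymo - 1e-9:
                kymo_t.append(self.t)
                for k in kymo:
                    kymo[k].append(self.state.conc(k))
                next_kymo += sch.kymo_every
            if self.t >= next_snap - 1e-9:
                snap_t.append(self.t)
                snaps.append(self.mesh.membrane.copy())
                next_snap += sch.snapshot_every
            self.step()
        if self.t >= next_rec - 1e-9:
            record(self.t)

        src = self.env.active_sources(t_end)
        return SimulationOutput(
            t=np.asarray(times),
            centroid=np.asarray(cents),
            filgap_c=np.asarray(fils),
            bound_filgap=np.asarray(bounds),
            frac_fast=np.asarray(fracs),
            kymo_times=np.asarray(kymo_t),
            kymographs={k: np.asarray(v) for k, v in kymo.items()},
            snapshot_times=np.asarray(snap_t),
            snapshots=snaps,
            source_position=(src[0].position.copy() if src else None),
            totals_start=totals_start,
            totals_end=self.totals(),
            config=cfg.to_dict(),
            master_seed=self.master_seed,
        )

    # -- polarity -------------------------------------------------------------

    def polarity_direction(self, recent_centroids: np.ndarray | None = None
                           ) -> np.ndarray:
        """Unit vector of the cell's current polarity: recent centroid motion
        if it is appreciable, otherwise the outward normal at the PIP3
        maximum."""
        if recent_centroids is not None and len(recent_centroids) >= 2:
            d = recent_centroids[-1] - recent_centroids[0]
            n = float(np.hypot(*d))
            if n > 0.05:
                return d / n
        geom = compute_geometry(self.mesh)
        i = int(np.argmax(self.state.conc("pip3")))
        return geom.normals[i]


def _rotate(u: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])


def run_experiment(
    protocol: str,
    overrides: dict | None = None,
    master_seed: int = 0,
    config: SimConfig | None = None,
    **kwargs,
):
    """Execute one of the study protocols and return its output.

    random_migration  stimulus-free run (default 900 s).
    gradient          spontaneous phase to ``stimulus_onset`` (default
                      500 s), then a point source giving
                      ``gradient_percent`` across the cell, placed at
                      ``gradient_angle_deg`` relative to the polarity the
                      cell holds at onset; runs to ``t_end``.
    mutant_sweep      gradient protocol for each value of
                      kwargs['param'] ('filgap' or 'pi3k') over
                      kwargs['values'] (μM); aggregates late-stage speed/CI.
    obstacle_ring     spontaneous migration inside an obstacle ring, then a
                      gradient stimulus from outside the ring.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    cfg = apply_overrides(config or SimConfig(), overrides)

    if protocol == "random_migration":
        simu = Simulation(cfg, master_seed)
        return simu.run(kwargs.get("t_end", cfg.schedule.t_end))

    if protocol == "gradient":
        return _run_gradient(cfg, master_seed, **kwargs)

    if protocol == "mutant_sweep":
        return _run_sweep(cfg, master_seed, **kwargs)

    return _run_obstacle_ring(cfg, master_seed, **kwargs)


def _run_gradient(cfg: SimConfig, master_seed: int,
                  t_end: float | None = None) -> SimulationOutput:
    sch = cfg.schedule
    onset = sch.stimulus_onset if sch.stimulus_onset is not None else 500.0
    t_end = t_end if t_end is not None else max(sch.t_end, onset + 1600.0)

    simu = Simulation(cfg, master_seed)
    # phase A: spontaneous migration, recorded on the same cadence as the
    # main run so the stitched trajectory is uniformly sampled
    cad = sch.record_every
    hist_t, hist_c = [], []
    while simu.t < onset - 1e-9:
        if not hist_t or simu.t - hist_t[-1] >= cad - 1e-9:
            hist_t.append(simu.t)
            hist_c.append(simu.centroid())
        simu.step()
    recent = np.asarray([c for ht, c in zip(hist_t, hist_c)
                         if ht >= onset - 60.0])
    polarity = simu.polarity_direction(recent)
    direction = _rotate(polarity, sch.gradient_angle_deg)
    source = place_source_for_gradient(
        sch.gradient_percent, direction, simu.centroid(),
        cfg.mesh.diameter, onset=onset,
        concentration_at_cell=sch.concentration_at_cell)
    simu.env.sources.append(source)
    # phase B: recorded run to t_end (recording restarts at onset; the
    # scalar series below covers the whole run via a fresh recorder)
    out = simu.run(t_end)
    # prepend nothing: out.t starts at onset; stitch the phase-A history in
    tA = np.asarray(hist_t)
    cA = np.asarray(hist_c)
    out.t = np.concatenate([tA, out.t])
    out.centroid = np.concatenate([cA, out.centroid])
    nA = len(tA)
    out.filgap_c = np.concatenate([np.full(nA, np.nan), out.filgap_c])
    out.bound_filgap = np.concatenate([np.full(nA, np.nan), out.bound_filgap])
    out.frac_fast = np.concatenate([np.full(nA, np.nan), out.frac_fast])
    return out


def _run_sweep(cfg: SimConfig, master_seed: int, param: str = "filgap",
               values=(0.0, 0.12, 0.4, 0.8, 1.2), seeds: int = 3,
               late_window: float = 500.0, t_end: float | None = None) -> dict:
    key = {"filgap": "mechano.filgap_total",
           "pi3k": "signaling.n_pi3k_total"}[param]
    results = {}
    for v in values:
        if param == "pi3k":
            ov = {key: int(round(v * sig.COUNTS_PER_UM))}
        else:
            ov = {key: float(v)}
        speeds, cis = [], []
        for s in range(seeds):
            out = run_experiment("gradient", ov,
                                 master_seed=master_seed + s, config=cfg,
                                 t_end=t_end)
            tmax = out.t[-1]
            speeds.append(out.speed().mean(t_min=tmax - late_window))
            cis.append(out.ci().mean(t_min=tmax - late_window))
        results[v] = {"speed": float(np.mean(speeds)),
                      "ci": float(np.mean(cis))}
    return results


def _run_obstacle_ring(cfg: SimConfig, master_seed: int, n_obstacles: int = 6,
                       ring_radius: float = 20.0, obstacle_radius: float = 5.0,
                       t_end: float = 1500.0) -> SimulationOutput:
    from .environment import obstacle_ring

    sch = cfg.schedule
    onset = sch.stimulus_onset if sch.stimulus_onset is not None else 500.0
    env = Environment(obstacles=obstacle_ring(
        (0.0, 0.0), n_obstacles, ring_radius, obstacle_radius))
    simu = Simulation(cfg, master_seed, environment=env)
    while simu.t < onset - 1e-9:
        simu.step()
    polarity = simu.polarity_direction()
    source = place_source_for_gradient(
        max(sch.gradient_percent, 5.0), polarity, simu.centroid(),
        cfg.mesh.diameter, onset=onset,
        concentration_at_cell=sch.concentration_at_cell)
    # put the source outside the ring along the polarity direction
    d = float(np.hypot(*(source.position - simu.centroid())))
    if d < 2 * ring_radius:
        source.position = simu.centroid() + polarity * 2 * ring_radius
    simu.env.sources.append(source)
    return simu.run(t_end)
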