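"""Three-layer signaling network on the periodic 1D membrane lattice.

Layers, top to bottom:

1. GPCR / balanced inactivation — a membrane activator (G_βγ-derived, read
   out as PAK1 activity E_p) is produced locally from the attractant signal,
   while an inhibitor produced at the same total rate is routed through the
   spatially uniform cytosol and returns to the membrane (G_α-derived, read
   out as Lsc1 activity E_ρ).  Activator and membrane inhibitor annihilate
   mutually, so the activator survives where the signal is strongest and the
   inhibitor where it is weakest.  The layer is closed without a stimulus.

2. Rac/RhoA — active membrane-bound GTPase G ∈ {R, ρ} obeys
   ∂G/∂t = D_m ∇²G + P_G·G_i − δ_G·G + Q_G·G  with activation
   P_R = I_R + α·E_p and P_ρ = I_ρ + τ·E_ρ, inactive pools G_i uniform in
   the cytosol and set by conservation.  Q_R = −Q_ρ is the FilGAP-mediated
   antagonism (first-order ultrasensitive switch in [FilGAP]·[PIP3]).

3. Phosphoinositides — a closed PIP3 + PIP2 pool interconverted by PI3K
   (PIP2→PIP3) and PTEN (PIP3→PIP2) whose membrane translocation is
   simulated by a Monte-Carlo scheme: enzymes bind preferentially where
   their target lipid (and the corresponding GTPase) is enriched, which is
   the positive feedback that forms and sustains a PIP3 patch.

Species are stored as *amounts* per node control volume; concentrations are
amount / arc length, so membrane stretching dilutes and compression
concentrates without any artificial mass change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import IntegrityError, shift_down, shift_up

__all__ = [
    "MembraneState",
    "CytosolState",
    "SignalingParams",
    "diffuse_periodic_1d",
    "gpcr_step",
    "filgap_antagonism",
    "rac_rho_step",
    "pi_step",
    "make_uniform_state",
]

#: molecule count corresponding to 1 μM of a translocating enzyme species
COUNTS_PER_UM = 15000.0


@dataclass
class SignalingParams:
    """Kinetic constants of the three signaling layers (μm, s, μM units)."""

    # shared
    D_m: float = 0.5          # membrane diffusivity, μm²/s
    dt_chem: float = 1.0      # chemistry master step, s
    sigma_noise: float = 0.5  # endogenous multiplicative noise amplitude

    # GPCR / balanced inactivation layer
    k_s: float = 1.0          # activator+inhibitor production per signal, 1/s
    k_deg: float = 0.2        # membrane degradation, 1/s
    k_ann: float = 500.0      # activator–inhibitor annihilation, 1/(μM·s)
    k_onB: float = 1.0        # cytosolic inhibitor membrane-on rate, 1/s

    # Rac/RhoA layer
    I_R: float = 0.10         # baseline Rac activation, 1/s
    I_rho: float = 0.10       # baseline RhoA activation, 1/s
    alpha: float = 0.7        # Rac activation by PAK1 (E_p), 1/(μM·s)
    tau: float = 0.03         # RhoA activation by Lsc1 (E_ρ), 1/(μM·s)
    delta_G: float = 0.10     # GAP-mediated baseline inactivation, 1/s
    pip3_rac_feedback: float = 0.0   # max PIP3->Rac GEF activation, 1/s
    pip3_rac_half: float = 3.0       # PIP3 level half-activating that feedback
    A_G: float = 50.0         # antagonism switch steepness (dimensionless)
    b: float = 40.0           # antagonism signal impact, 1/(μM·conc)
    R_tot: float = 62.8       # total Rac amount (conc × length units)
    rho_tot: float = 62.8     # total RhoA amount

    # phosphoinositide layer
    PI_tot: float = 125.7     # total PIP3+PIP2 amount (≈ 2 conc units × L)
    k_cat3: float = 0.10      # PI3K catalysis, μm/(molecule·s)
    k_cat2: float = 0.10      # PTEN catalysis, μm/(molecule·s)
    k_on: float = 0.5         # enzyme membrane binding propensity, 1/s
    k_off: float = 0.4        # enzyme unbinding, 1/s
    bind_coop: float = 2.5    # cooperativity of PIP3-mediated PI3K recruitment
    bind_coop_pten: float = 1.5  # cooperativity of PIP2-mediated PTEN recruitment
    cat_half_rac: float = 0.45  # Rac level half-activating PI3K catalysis (0 = off)
    cat_half_rho: float = 0.0   # RhoA level half-activating PTEN catalysis (0 = off)
    cat_floor: float = 0.4      # GTPase-independent catalysis floor
    bias_half_rac: float = 0.45  # Rac level half-saturating the recruitment bias
    bias_half_rho: float = 3.0  # RhoA level half-saturating the recruitment bias
    bias_floor: float = 0.04    # GTPase-independent recruitment floor
    w_R3: float = 6.0         # Rac bias of PI3K recruitment (dimensionless)
    w_rho2: float = 6.0       # RhoA bias of PTEN recruitment (dimensionless)
    w_gpcr: float = 10.0      # direct receptor bias of enzyme recruitment, 1/μM
    n_pi3k_total: int = 600   # PI3K molecule count (0.04 μM × COUNTS_PER_UM)
    n_pten_total: int = 600   # PTEN molecule count (0.04 μM)

    def __post_init__(self) -> None:
        if self.A_G <= 0:
            raise ValueError("A_G must be positive")
        for name in ("D_m", "k_s", "k_deg", "k_ann", "k_onB", "I_R", "I_rho",
                     "alpha", "tau", "delta_G", "b", "k_cat3", "k_cat2",
                     "k_on", "k_off", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class MembraneState:
    """Per-membrane-node species amounts plus the node arc lengths.

    ``arc`` is the control-volume length attached to each node (half of each
    incident membrane edge); concentration = amount / arc.
    """

    arc: np.ndarray          # (Nm,) μm
    s: np.ndarray            # attractant signal at nodes (concentration)
    a_act: np.ndarray        # activator amount (G_βγ → PAK1)
    b_m: np.ndarray          # membrane inhibitor amount (G_α → Lsc1)
    rac: np.ndarray          # active Rac amount
    rho: np.ndarray          # active RhoA amount
    pip3: np.ndarray         # PIP3 amount
    pip2: np.ndarray         # PIP2 amount
    n_pi3k: np.ndarray       # bound PI3K per node (counts)
    n_pten: np.ndarray       # bound PTEN per node (counts)

    def conc(self, name: str) -> np.ndarray:
        return getattr(self, name) / self.arc


@dataclass
class CytosolState:
    """Spatially uniform cytosolic pools.

    The canonical state for the inactive GTPases is the *amount*
    (``rac_i_amt``, ``rho_i_amt``); the concentrations ``rac_i``/``rho_i``
    are these amounts divided by the current membrane length, refreshed on
    every step, so membrane growth never creates or destroys material.
    """

    rac_i: float             # inactive Rac concentration
    rho_i: float             # inactive RhoA concentration
    rac_i_amt: float = 0.0   # inactive Rac amount (canonical)
    rho_i_amt: float = 0.0   # inactive RhoA amount (canonical)
    b_c: float = 0.0         # cytosolic inhibitor concentration
    filgap_c: float = 0.0    # cytosolic FilGAP concentration, μM
    pi3k_free: float = 0     # free PI3K molecules
    pten_free: float = 0     # free PTEN molecules


def make_uniform_state(
    arc: np.ndarray, params: SignalingParams
) -> tuple[MembraneState, CytosolState]:
    """Symmetric initial condition: half of each GTPase pool active and
    uniform, the PI pool split evenly between PIP3 and PIP2, all enzymes
    free in the cytosol."""
    arc = np.asarray(arc, dtype=float)
    L = arc.sum()
    nm = len(arc)
    z = np.zeros(nm)
    state = MembraneState(
        arc=arc.copy(),
        s=z.copy(),
        a_act=z.copy(),
        b_m=z.copy(),
        rac=0.5 * params.R_tot * arc / L,
        rho=0.5 * params.rho_tot * arc / L,
        pip3=0.5 * params.PI_tot * arc / L,
        pip2=0.5 * params.PI_tot * arc / L,
        n_pi3k=np.zeros(nm),
        n_pten=np.zeros(nm),
    )
    cyt = CytosolState(
        rac_i=0.5 * params.R_tot / L,
        rho_i=0.5 * params.rho_tot / L,
        rac_i_amt=0.5 * params.R_tot,
        rho_i_amt=0.5 * params.rho_tot,
        pi3k_free=float(params.n_pi3k_total),
        pten_free=float(params.n_pten_total),
    )
    return state, cyt


# ---------------------------------------------------------------------------
# 1D finite-difference diffusion on the non-uniform periodic membrane lattice
# ---------------------------------------------------------------------------

def diffuse_periodic_1d(
    amounts: np.ndarray, arc: np.ndarray, D: float, dt: float
) -> np.ndarray:
    """Conservative flux-form diffusion step; returns updated amounts.

    Node i carries ``amounts[i]`` in a control volume of length ``arc[i]``;
    the flux between neighbors is D·(c_{i+1} − c_i) / d_{i+1/2} with
    d_{i+1/2} = (arc_i + arc_{i+1})/2.  Sub-steps internally to satisfy the
    explicit stability bound, so any dt is safe.  Total amount is conserved
    to machine precision.
    """
    if D == 0.0 or dt == 0.0:
        return amounts.copy()
    arc = np.asarray(arc, dtype=float)
    if np.any(arc <= 0):
        raise IntegrityError("non-positive arc length")
    dist = 0.5 * (arc + shift_up(arc))             # node i to node i+1
    # explicit stability: dt <= arc_i / (D (1/d_left + 1/d_right))
    inv = 1.0 / dist
    bound = (arc / (D * (inv + shift_down(inv)))).min()
    n_sub = max(1, int(np.ceil(dt / (0.9 * bound))))
    h = dt / n_sub
    a = amounts.astype(float).copy()
    for _ in range(n_sub):
        c = a / arc
        flux = D * (shift_up(c) - c) / dist         # flux i -> from i+1 side
        a += h * (flux - shift_down(flux))
    return a


# ---------------------------------------------------------------------------
# Layer 1: GPCR balanced inactivation
# ---------------------------------------------------------------------------

def gpcr_step(
    state: MembraneState,
    cytosol: CytosolState,
    stimulus: np.ndarray,
    params: SignalingParams,
    dt: float,
) -> None:
    """Advance activator A, membrane inhibitor B_m and cytosolic inhibitor
    B_c by one step (in place).

    dA_i/dt  = k_s S_i − k_deg A_i − k_ann A_i B_m,i + D_m ∇²A
    dB_c/dt  = (k_s/L) Σ S_i d_i − k_onB B_c
    dB_m/dt  = k_onB B_c − k_deg B_m − k_ann A B_m

    Production of activator and inhibitor is balanced: both integrate to
    k_s Σ S_i d_i per unit time.  A Patankar-type semi-implicit update keeps
    every species nonnegative without clipping mass into existence.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if np.any(stimulus < 0):
        raise IntegrityError("negative stimulus concentration")
    arc = state.arc
    L = arc.sum()
    a = state.a_act / arc
    bm = state.b_m / arc

    a_new = (a + dt * params.k_s * stimulus) / (
        1.0 + dt * (params.k_deg + params.k_ann * bm)
    )
    bm_new = (bm + dt * params.k_onB * cytosol.b_c) / (
        1.0 + dt * (params.k_deg + params.k_ann * a)
    )
    prod_c = params.k_s * float(np.sum(stimulus * arc)) / L
    cytosol.b_c = (cytosol.b_c + dt * prod_c) / (1.0 + dt * params.k_onB)

    state.a_act = diffuse_periodic_1d(a_new * arc, arc, params.D_m, dt)
    state.b_m = bm_new * arc


# ---------------------------------------------------------------------------
# Layer 2: Rac / RhoA
# ---------------------------------------------------------------------------

def filgap_antagonism(
    filgap_c: float, pip3: np.ndarray, params: SignalingParams
) -> tuple[np.ndarray, np.ndarray]:
    """FilGAP-mediated antagonism Q_R = −1/(1 + A_G exp(−b·[FilGAP]·[PIP3])),
    Q_ρ = −Q_R.  Q_R ∈ (−1, 0): Rac is suppressed (and RhoA boosted) where
    cytosolic FilGAP meets membrane PIP3."""
    pip3 = np.asarray(pip3, dtype=float)
    q_r = -1.0 / (1.0 + params.A_G * np.exp(-params.b * filgap_c * pip3))
    return q_r, -q_r


def rac_rho_step(
    state: MembraneState,
    cytosol: CytosolState,
    q_r: np.ndarray,
    q_rho: np.ndarray,
    params: SignalingParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> None:
    """Advance active Rac/RhoA and their conserved inactive pools (in place).

    Activation draws on the uniform inactive pool with rate
    (I + α·E)(1 + ξ), ξ the endogenous multiplicative noise; inactivation is
    δ_G plus the antagonism term Q_G.  The inactive pools are recomputed
    from the conservation law after each sub-step, so the totals are exact.
    """
    arc = state.arc
    L = arc.sum()
    e_p = state.a_act / arc
    e_rho = state.b_m / arc

    act_r = params.I_R + params.alpha * e_p
    if params.pip3_rac_feedback > 0:
        # PIP3-dependent GEF recruitment: the positive arm of the
        # Rho GTPase <-> phosphoinositide feedback loop
        p3 = state.pip3 / arc
        x = (p3 / params.pip3_rac_half) ** 2
        act_r = act_r + params.pip3_rac_feedback * x / (1.0 + x)
    act_rho = params.I_rho + params.tau * e_rho
    if params.sigma_noise > 0 and rng is not None:
        act_r = act_r * np.clip(
            1.0 + params.sigma_noise * rng.standard_normal(len(arc)), 0.0, None
        )
        act_rho = act_rho * np.clip(
            1.0 + params.sigma_noise * rng.standard_normal(len(arc)), 0.0, None
        )

    # sub-step so that neither pool can be overdrawn in one explicit draw
    max_rate = max(float(act_r.max()), float(act_rho.max()),
                   float(q_rho.max()), 1e-12)
    n_sub = max(1, int(np.ceil(dt * max_rate / 0.5)))
    h = dt / n_sub
    pool_r = cytosol.rac_i_amt
    pool_p = cytosol.rho_i_amt
    r = state.rac / arc
    p = state.rho / arc
    for _ in range(n_sub):
        # membrane recruitment (activation, and the positive Q_ρ branch of
        # the antagonism) draws on the finite cytosolic pool: inflows are
        # scaled down when a step would overdraw it, and every transfer is
        # an exact amount exchange between membrane and pool
        in_r = h * act_r * (pool_r / L)
        in_p = h * (act_rho * (pool_p / L) + q_rho * p)
        need_r = float(np.sum(in_r * arc))
        need_p = float(np.sum(in_p * arc))
        if need_r > pool_r:
            in_r *= pool_r / need_r
            need_r = pool_r
        if need_p > pool_p:
            in_p *= pool_p / need_p
            need_p = pool_p
        r = (r + in_r) / (1.0 + h * (params.delta_G - q_r))
        p = (p + in_p) / (1.0 + h * params.delta_G)
        pool_r += float(np.sum(h * (params.delta_G - q_r) * r * arc)) - need_r
        pool_p += float(np.sum(h * params.delta_G * p * arc)) - need_p
    state.rac = r * arc
    state.rho = p * arc
    cytosol.rac_i_amt = pool_r
    cytosol.rho_i_amt = pool_p
    cytosol.rac_i = pool_r / L
    cytosol.rho_i = pool_p / L
    state.rac = diffuse_periodic_1d(state.rac, arc, params.D_m, dt)
    state.rho = diffuse_periodic_1d(state.rho, arc, params.D_m, dt)


# ---------------------------------------------------------------------------
# Layer 3: phosphoinositides with Monte-Carlo PI3K/PTEN translocation
# ---------------------------------------------------------------------------

def _bind_unbind(
    n_bound: np.ndarray,
    n_free: float,
    p_bind: np.ndarray,
    k_off: float,
    dt: float,
    rng: np.random.Generator | None,
    stochastic: bool,
) -> tuple[np.ndarray, float]:
    """One translocation step for a single enzyme species.

    ``p_bind[i]`` is the probability, per free molecule and per step, of
    binding node i; bound molecules unbind with probability
    1 − exp(−k_off dt).  The step is subdivided internally whenever the
    total binding probability approaches 1.
    """
    p_tot = float(p_bind.sum())
    n_sub = max(1, int(np.ceil(p_tot / 0.5)), int(np.ceil(k_off * dt / 0.5)))
    p = p_bind / n_sub
    ps = float(p.sum())
    p_off = -np.expm1(-k_off * dt / n_sub)
    if stochastic:
        if rng is None:
            raise ValueError("stochastic translocation requires an rng")
        bound = n_bound.astype(np.int64)
        free = int(n_free)
        for _ in range(n_sub):
            unbound = rng.binomial(bound, p_off)
            if ps > 0 and free >= 1:
                n_bind = rng.binomial(free, ps)
                placed = rng.multinomial(n_bind, p / ps)
            else:
                n_bind, placed = 0, 0
            bound = bound - unbound + placed
            free = free - n_bind + int(unbound.sum())
        return bound.astype(float), float(free)
    bound = n_bound.astype(float)
    free = float(n_free)
    for _ in range(n_sub):
        unbound = bound * p_off
        placed = free * p
        bound = bound - unbound + placed
        free = free - float(np.sum(placed)) + float(np.sum(unbound))
    return bound, free


def pi_step(
    state: MembraneState,
    cytosol: CytosolState,
    params: SignalingParams,
    dt: float,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> None:
    """Advance PIP3/PIP2 and PI3K/PTEN translocation by one step (in place).

    PI3K binds where PIP3 (boosted by active Rac) is enriched and converts
    PIP2 → PIP3 at rate k_cat3·n/d; PTEN is the mirror image via PIP2 and
    RhoA.  The PIP3 + PIP2 total and the enzyme counts are conserved
    exactly; with ``stochastic=False`` the Monte-Carlo draws are replaced by
    their expectations (the deterministic mean-field limit).
    """
    arc = state.arc

    # --- translocation -----------------------------------------------------
    # per-molecule binding probability: dt·k_on·(lipid share)·(1 + w·GTPase);
    # the lipid share is cooperative (weight ∝ d·c^γ): recruitment by lipid
    # microdomains is superlinear in the local concentration, which is what
    # makes the uniform state linearly unstable and lets a patch self-amplify
    w3 = arc * (state.pip3 / arc) ** params.bind_coop
    w2 = arc * (state.pip2 / arc) ** params.bind_coop_pten
    # GTPase bias of recruitment: an ultrasensitive gate with a small
    # GTPase-independent floor.  A front whose Rac has been selectively
    # crushed by FilGAP loses its PI3K share to the rest of the membrane;
    # when Rac is suppressed (or elevated) uniformly the factor cancels out
    # of the normalized shares and recruitment follows the lipids alone.
    r = state.rac / arc
    rho = state.rho / arc
    x3 = (r / params.bias_half_rac) ** 4
    x2 = (rho / params.bias_half_rho) ** 4
    bias3 = params.bias_floor + params.w_R3 * x3 / (1.0 + x3)
    bias2 = params.bias_floor + params.w_rho2 * x2 / (1.0 + x2)
    if params.w_gpcr > 0:
        # direct receptor-proximal recruitment (G_βγ -> PI3K at the
        # attractant-facing side, G_α -> PTEN at the far side): gives an
        # applied gradient authority over where the enzymes rebind
        bias3 = bias3 * (1.0 + params.w_gpcr * state.a_act / arc)
        bias2 = bias2 * (1.0 + params.w_gpcr * state.b_m / arc)
    w3 = w3 * bias3
    w2 = w2 * bias2
    tot3 = float(w3.sum())
    tot2 = float(w2.sum())
    share3 = w3 / tot3 if tot3 > 0 else np.zeros_like(arc)
    share2 = w2 / tot2 if tot2 > 0 else np.zeros_like(arc)
    p3 = dt * params.k_on * share3
    p2 = dt * params.k_on * share2
    state.n_pi3k, cytosol.pi3k_free = _bind_unbind(
        state.n_pi3k, cytosol.pi3k_free, p3, params.k_off, dt, rng, stochastic)
    state.n_pten, cytosol.pten_free = _bind_unbind(
        state.n_pten, cytosol.pten_free, p2, params.k_off, dt, rng, stochastic)

    # --- catalysis (exact antisymmetric transfer conserves the pool) -------
    # bound PI3K is activated by local active Rac, PTEN by active RhoA
    # (saturable); this is the hinge through which the FilGAP antagonism
    # shuts down conversion at an over-strained front
    rate3 = params.k_cat3 * state.n_pi3k / arc      # 1/s, PIP2 -> PIP3
    rate2 = params.k_cat2 * state.n_pten / arc      # 1/s, PIP3 -> PIP2
    if params.cat_half_rac > 0:
        x = (state.rac / arc / params.cat_half_rac) ** 4
        rate3 = rate3 * (params.cat_floor + (1 - params.cat_floor) * x / (1 + x))
    if params.cat_half_rho > 0:
        x = (state.rho / arc / params.cat_half_rho) ** 4
        rate2 = rate2 * (params.cat_floor + (1 - params.cat_floor) * x / (1 + x))
    max_rate = max(float(rate3.max()), float(rate2.max()), 1e-12)
    n_sub = max(1, int(np.ceil(dt * max_rate / 0.5)))
    h = dt / n_sub
    for _ in range(n_sub):
        transfer = h * (rate3 * state.pip2 - rate2 * state.pip3)
        transfer = np.clip(transfer, -state.pip3, state.pip2)
        state.pip3 = state.pip3 + transfer
        state.pip2 = state.pip2 - transfer

    # --- diffusion ----------------------------------------------------------
    state.pip3 = diffuse_periodic_1d(state.pip3, arc, params.D_m, dt)
    state.pip2 = diffuse_periodic_1d(state.pip2, arc, params.D_m, dt)


def rescale_amounts(state: MembraneState, new_arc: np.ndarray) -> None:
    """Update the arc lengths after a mechanics move.

    Amounts are canonical, so nothing is transferred: stretching a control
    volume dilutes its concentration, compression concentrates it, and all
    length-weighted totals are untouched.
    """
    state.arc = np.asarray(new_arc, dtype=float).copy()
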