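# Model and methods

## Overview

The cell is a closed chain of `N_m = 45` membrane nodes (10 μm diameter)
enclosing `N_i = 421` lamellipod nodes, all joined by the Delaunay
triangulation of the node set, re-computed every step and clipped to the
membrane polygon.  One master step of `dt = 1 s` advances, in order: the
chemoattractant sampling and GPCR layer (only while a stimulus is
scheduled), the Rho GTPase layer, the phosphoinositide layer, the
strain-gated FilGAP exchange, the membrane mechanics, the dilution
bookkeeping, the quasi-static lamellipod relaxation, and the
retriangulation with crosslink transfer.

All membrane species are stored as *amounts* per node control volume (half
of each incident membrane edge); concentrations are amount / arc length.
Stretching a piece of membrane therefore dilutes what sits on it and
compression concentrates it, with no artificial mass change — this is the
bookkeeping through which shape feeds back on signaling.

## Signaling

**GPCR / balanced inactivation.**  The attractant signal S_i produces a
membrane activator A (read out as PAK1 activity, E_p) and, at the same
total rate, a cytosolic inhibitor that returns uniformly to the membrane
(read out as Lsc1 activity, E_ρ).  A and the membrane inhibitor annihilate
at rate `k_ann = 500 /(μM·s)`; in this strong-annihilation regime the
activator tracks `max(S_i − S̄, 0)` — common-mode rejection — so a 2%
gradient is converted into a front/back activity difference without raising
the global level.  The layer is closed when no source is active.

**Rho GTPases.**  Active membrane-bound Rac and RhoA obey

    ∂G/∂t = D_m ∇²G + P_G (1 + ξ) G_i − δ_G G + Q_G G,

with `P_R = I_R + α·E_p`, `P_ρ = I_ρ + τ·E_ρ`, the inactive pools `G_i`
uniform in the cytosol and bound to the membrane totals by exact
conservation (every activation or inactivation event is a bookkept amount
transfer).  ξ is zero-mean multiplicative noise of amplitude
`sigma_noise = 0.5` applied to the activation propensity each step — the
endogenous stochasticity that seeds spontaneous polarization.  The
antagonism term is the ultrasensitive switch

    Q_R = −Q_ρ = −1 / (1 + A_G · exp(−b·[FilGAP]·[PIP3])),

with the cytosolic FilGAP pool as [FilGAP], so locality enters through
PIP3: released FilGAP suppresses Rac (and boosts RhoA) exactly where the
membrane is PIP3-rich — the front.

**Phosphoinositides.**  PIP3 + PIP2 form a closed pool interconverted by
PI3K (PIP2→PIP3) and PTEN (PIP3→PIP2).  Enzyme molecules (600 each,
0.04 μM at 15 000 molecules/μM) translocate by a Monte-Carlo scheme: each
free molecule binds node i with probability `dt·k_on·w_i/Σw` and unbinds
with rate `k_off`.  The binding weight is

    w_i  ∝  d_i · c_i^γ · (floor + w_G·act(G_i)) · (1 + w_gpcr·E_i)

where `c` is the enzyme's target lipid (PIP3 for PI3K at cooperativity
γ = 2.5; PIP2 for PTEN at γ = 1.5), `act(G) = G⁴/(G_½⁴ + G⁴)` is an
ultrasensitive gate on the corresponding GTPase (Rac for PI3K, RhoA for
PTEN), and E is the receptor-proximal activity (G_βγ recruits PI3K on the
attractant-facing side, G_α recruits PTEN on the far side).  PI3K
catalysis is additionally Rac-activated with a floor:
`k_cat,eff = k_cat·(0.4 + 0.6·act(Rac))`.

Three design points deserve emphasis, because they are where this
implementation had to commit beyond the printed equations:

1. *Cooperative recruitment (γ > 1) is the polarization engine.*  With
   strictly linear lipid shares and equal enzyme pools, the mean-field
   patterning terms of PI3K and PTEN cancel identically at every profile —
   the deterministic system cannot polarize at all.  A superlinear share
   makes the uniform state linearly unstable with growth rate ∝ (γ − 1),
   producing the self-amplifying PIP3 patch; γ = 1 recovers the linear
   form and is used as the neutral reference in the symmetry tests.
2. *The GTPase gates are the brake's lever.*  Without them, FilGAP's Q_R
   only lowers active Rac, which nothing downstream would notice; with
   them, a Rac-crushed front loses its PI3K share and its conversion rate,
   and the patch collapses.  The floors (recruitment 0.04, catalysis 0.4)
   are equally essential: under a *saturated* brake ([FilGAP] ≥ ~0.5 μM,
   Q ≈ −1 everywhere) the gates become spatially uniform and cancel out of
   the normalized shares, so polarity then depends on raw enzyme abundance
   — which is how a 3× PI3K dose overrides even a maximal brake while the
   wildtype dose cannot.
3. *Receptor-proximal recruitment gives gradients authority during
   repolarization.*  After the brake kills a front, the old PIP3 remnant
   would otherwise re-seed the old direction (lipid memory); the direct
   G_βγ→PI3K / G_α→PTEN bias lets an opposing gradient win that race,
   which is what makes a 5% reversal reliable.

## Mechanosensing

Each (triangle, corner) of the clipped triangulation is an FLNa crosslink
with capacity `m0` (the total budget divided evenly over corners, 80%
bound at start) holding `m` FilGAP molecules:

    dm_i/dt = A·w·(m_i0 − m_i)/(Σm_i0 − Σm_i)
              − [k_slow + (k_fast − k_slow)·sng(Δθ_i)] · m_i

`sng` is 0 while the angular strain Δθ_i (current minus reference corner
angle) lies in the closed band [−0.3, 0.3] rad and 1 outside it.  Release
is first order in `m_i` (a bare-rate release would drive occupancies
negative), the return flux is gated by cytosolic availability
`w = [FilGAP]_c/[FilGAP]_total`, and every exchanged molecule is an exact
budget transfer, so bound + cytosolic FilGAP is conserved to machine
precision, including across retriangulations (corners of destroyed
triangles surrender their load to the cytosol; new corners start empty at
the mean capacity).

The reference angles are not frozen: they relax toward the current angles
with time constant `tau_ref = 60 s`.  The lamellipod springs have zero
rest length, so *every* shape is an elastic equilibrium; with frozen
references a cell that stops deforming would keep its strain forever, the
band would never be re-entered, FilGAP would never rebind, and the cell
would deadlock.  With slow remodeling, strain measures the recent
deformation rate: a protruding, turning cell keeps its crosslinks strained
and releasing; a stalled cell recovers within a minute and rebinds.  This
is what produces the velocity → cytosolic-FilGAP lag of tens of seconds in
spontaneous runs.

## Mechanics

Membrane node forces: Hookean spring + dashpot per edge (k = 3 nN/μm,
η = 1 nN·s/μm, rest length 0.698 μm = the resting spacing), a global
perimeter tension `k_perim·(P/P0 − 1)` modelling the finite membrane
reservoir, a uniform pressure `k_area·(A_target − A)` applied per edge
(`p·ℓ_e·n̂_e`, so the pressure force sums to exactly zero over the closed
contour — it can reshape but never translate the cell), a drag against the
nearest lamellipod node's velocity, and the active forces

    F_pro = f_pro · H(PIP3) · gate(PIP3/⟨PIP3⟩) · n̂  (outward)
    F_cont = f_cont · H(PIP2) · gate(PIP2/⟨PIP2⟩) · (−n̂)

with `H` a Hill response (exponent 6, half-saturation 3.3 / 2.8 —
representing the saturation of the F-actin density that PIP3 can recruit)
and `gate` a linear ramp from 0 at the spatial mean to 1 at 10% above it
(polarity-relative forcing; the continuous ramp, unlike a hard step, does
not convert float-epsilon spread in a uniform field into finite forces).
The force profile is smoothed over neighboring nodes (three passes of a
1/4–1/2–1/4 kernel): a pseudopod has finite width, and without the
smoothing the membrane ruffles node-by-node instead of protruding
coherently.  The active-force fields are per-node amounts on the resting
arc scale rather than concentrations, so mechanical compression of the
rear cannot bootstrap a contraction front out of nothing.

Node motion is explicit Euler on `v = F/μ`, sub-stepped 16× per master
step: the stiffest membrane mode (≈ 16 s⁻¹ for these spring constants)
must stay inside the explicit stability bound, and relying on the
displacement cap instead (which also exists, 0.2 membrane spacings per
sub-move, as a safety) would mask the instability as sawtooth noise.
Interior nodes are relaxed to the zero-net-spring condition each step by a
direct sparse solve over the full (unclipped) Delaunay adjacency — the
unclipped graph is always connected, whereas the clipped lamellipod can
transiently orphan a node near a concavity.

## Environment and metrics

Point sources have the steady far field `C = C0·r0/max(r, r0)`; gradient
strength is parameterized as the percentage concentration difference
across one cell diameter at the cell, `p = 100·(C_front − C_back)/C_mid`,
with closed-form source placement (for the optional exponential field the
decay length is solved instead, since there the percentage is independent
of distance).  Sources are normalized to unit concentration at the cell at
placement, so protocols differ only in gradient strength and direction.
Obstacles are rigid frictionless disks enforced by radial projection.

Centroid speed is the central difference of the polygon centroid at the
25 s trajectory cadence, boxcar-smoothed over 60 s, in μm/min; sampling at
imaging-like cadence keeps sub-sampling membrane flicker out of the speed
estimate.  The chemotaxis index is the windowed mean cosine between the
velocity and the direction to the source (gaps where the smoothed speed is
below 0.2 μm/min); a net-displacement-over-path-length variant is provided
as `chemotaxis_index_displacement`.  The coverage ratio rasterizes the
union of cell footprints on a 0.25 μm grid over the obstacle-ring interior
(≤ 0.1% area error at cell scale).

## Default profile and calibration

Most rate constants and force magnitudes are not published quantities;
they ship as a single calibrated profile (every value overridable, see
`SimConfig`).  The calibration anchors, all reproduced by
`scripts/acceptance.py` with the shipped defaults, are: spontaneous
migration at ≈ 4 μm/min with a 50–100 s velocity→FilGAP lag and
single-patch polarization within 100 s; late-stage chemotactic speeds of
≈ 10 μm/min for the FilGAP-null cell, ≈ 3 μm/min at 0.12 μM FilGAP, and
≈ 10 μm/min at 0.12 μM PI3K against a 0.6 μM FilGAP brake; and full
reversal (CI → +1) under an opposing 5% gradient.  The qualitative logic
is fixed by the architecture — the brake cannot touch the FilGAP-null
cell, saturates into ineffectiveness at high FilGAP·PIP3, and is
overridden by enzyme abundance — so the calibration mainly sets scales:
`f_pro = 1.2 nN` puts the unbraked speed near 10 μm/min; `k_slow = 0.014/s`
(tonic in-band release) and the band ±0.3 rad set the braked duty cycle
near 40%; `b = 40`, `A_G = 50` place the antagonism switch between the
resting and released cytosolic FilGAP levels.

Problem sizes used throughout: the full 45 + 421-node cell, 900 s
spontaneous runs and 2100 s gradient runs (stimulus at 500 s), 10 seeds
per condition in the acceptance script and the acceptance tests, 20 seeds
for the polarization property.

## What the simulations do and do not show

The cell here is an abstraction: no adhesion dynamics, no explicit actin
or myosin fields, no nucleus, no hydrodynamics, and a strictly 2D,
fixed-node-count geometry.  The attractant field is static (no consumption
or obstacle shadowing).  Endogenous noise is a modeling primitive
(multiplicative activation noise plus enzyme shot noise), not derived from
molecular copy numbers.  Agreement of the migration statistics therefore
shows that this architecture — cooperative lipid-enzyme feedback plus a
strain-gated, conserved inhibitor budget — is sufficient to organize the
observed motility regimes; it does not validate the individual rate
constants, most of which are degenerate with one another at the level of
these observables.

Two numerical points worth knowing before extending the model:

* The uniform state is *deliberately* linearly unstable (the patch
  engine).  Consequently any floating-point implementation will amplify
  rounding error into a patch within a few e-folds even at zero noise.
  The discretization itself is certified symmetric in the neutral
  configuration (linear recruitment, no GTPase bias, no drag): there a
  zero-noise uniform run keeps every field bitwise uniform and the
  centroid stationary to < 1e-15 μm/step indefinitely.  Uniform-state
  control volumes snap to exactly uniform when the segment spread is below
  1e-12 relative, which is what makes the bitwise preservation possible.
* Near-degenerate Delaunay configurations can flip between triangulations
  on successive steps; all bookkeeping (FilGAP budget, reference angles)
  is transfer-exact under such flips, but the interior equilibrium jumps
  discontinuously, which enters the membrane only through the (small)
  lamellipod drag term.

Known limitations: the strain signal vanishes for a cell translating
perfectly rigidly (the quasi-static lamellipod carries no memory of
translation), so sustained FilGAP cycling relies on the shape actually
fluctuating — which it does at the default noise level; very soft
parameter settings (low `k_area`/`k_perim`) admit a two-patch stalemate
and an elongated slow-migration mode that the default profile avoids;
and `run_experiment("mutant_sweep", ...)` aggregates per-value statistics
but no confidence intervals.
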