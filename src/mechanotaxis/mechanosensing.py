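"""FLNa–FilGAP mechanosensing: strain-gated crosslink release.

Every (triangle, corner) of the lamellipodial network is an FLNa crosslink
site holding ``m`` FilGAP molecules out of a capacity ``m0``.  The angular
strain Δθ at the corner gates the release rate through a bandpass: inside
[β1, β2] the crosslink releases slowly (rate k_slow), outside it releases
fast (k_fast).  Released molecules join the uniform cytosolic pool, from
which they return to under-filled crosslinks in proportion to the local
capacity deficit.  The total FilGAP budget (bound + cytosolic) is conserved
exactly, including across retriangulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import CellMesh, corner_keys

__all__ = [
    "MechanoParams",
    "CrosslinkState",
    "classify_strain",
    "filgap_step",
    "rebind_capacity",
    "init_crosslinks",
    "FILGAP_COUNTS_PER_UM",
]

#: molecule count corresponding to 1 μM of total FilGAP
FILGAP_COUNTS_PER_UM = 3000.0


@dataclass
class MechanoParams:
    """FLNa–FilGAP pathway constants.

    A_ret        maximal total return flux to the network (molecules/s)
    k_slow       in-band (relaxed) release rate (1/s)
    k_fast       out-of-band (strained) release rate (1/s)
    beta1, beta2 strain band bounds (rad), closed interval
    filgap_total total FilGAP concentration (μM); 0 abolishes the pathway
    bound_fraction_init  fraction of the budget bound at t = 0
    tau_ref      FLNa network remodeling time (s): reference angles relax
                 toward the current angles with this constant, so the strain
                 of a resting cell decays ("mostly recovered"); <= 0 freezes
                 the reference configuration
    """

    A_ret: float = 30.0
    k_slow: float = 0.014
    k_fast: float = 0.12
    beta1: float = -0.3
    beta2: float = 0.3
    filgap_total: float = 0.12
    bound_fraction_init: float = 0.8
    tau_ref: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.k_slow < self.k_fast):
            raise ValueError("need 0 <= k_slow < k_fast")
        if self.beta1 >= self.beta2:
            raise ValueError("need beta1 < beta2")
        if self.filgap_total < 0:
            raise ValueError("filgap_total must be nonnegative")

    @property
    def total_molecules(self) -> float:
        return self.filgap_total * FILGAP_COUNTS_PER_UM


@dataclass
class CrosslinkState:
    """Per-(triangle, corner) FilGAP occupancy, aligned with mesh.triangles."""

    m: np.ndarray        # (T, 3) bound molecules
    m0: np.ndarray       # (T, 3) capacity
    keys: np.ndarray     # (T, 3) int64 corner identities (see mesh.corner_keys)

    def total_bound(self) -> float:
        return float(self.m.sum())


def init_crosslinks(
    mesh: CellMesh, params: MechanoParams
) -> tuple[CrosslinkState, float]:
    """Uniform initial occupancy: capacities split the total budget evenly
    across corners; ``bound_fraction_init`` of the budget starts bound and
    the rest is cytosolic.  Returns (state, cytosolic FilGAP in μM)."""
    shape = mesh.triangles.shape
    n_corners = shape[0] * 3
    total = params.total_molecules
    m0 = np.full(shape, total / n_corners if n_corners else 0.0)
    m = params.bound_fraction_init * m0
    filgap_c = (
        (total - m.sum()) / FILGAP_COUNTS_PER_UM if total > 0 else 0.0
    )
    return CrosslinkState(m=m, m0=m0, keys=corner_keys(mesh)), filgap_c


def classify_strain(
    delta_theta: np.ndarray, beta1: float, beta2: float
) -> np.ndarray:
    """Bandpass indicator: 0 (slow release) for β1 ≤ Δθ ≤ β2, else 1 (fast)."""
    dt = np.asarray(delta_theta)
    return ((dt < beta1) | (dt > beta2)).astype(np.int8)


def filgap_step(
    crosslinks: CrosslinkState,
    filgap_c: float,
    indicator: np.ndarray,
    params: MechanoParams,
    dt: float,
) -> float:
    """Advance bound FilGAP by one step (in place); returns new cytosolic
    concentration (μM).

    dm_i/dt = A_ret·w·(m0_i − m_i)/(Σm0 − Σm) − [k_slow + (k_fast−k_slow)·sng_i]·m_i

    with w = FilGAP_c / FilGAP_total scaling the return flux by cytosolic
    availability.  Release is first order in m_i so occupancies stay in
    [0, m0]; every molecule exchanged is an exact budget transfer.
    """
    total = params.total_molecules
    if total <= 0 or crosslinks.m.size == 0:
        return filgap_c
    k_rel = params.k_slow + (params.k_fast - params.k_slow) * indicator
    cyt = filgap_c * FILGAP_COUNTS_PER_UM
    # sub-step so no occupancy can overshoot its clip by more than ~1%
    n_sub = max(1, int(np.ceil(dt * params.k_fast / 0.1)),
                int(np.ceil(dt * params.A_ret / max(total * 0.05, 1e-12))))
    h = dt / n_sub
    m = crosslinks.m
    for _ in range(n_sub):
        deficit = crosslinks.m0 - m
        dsum = float(deficit.sum())
        if dsum > 1e-12 and cyt > 0:
            w = cyt / total
            ret = min(params.A_ret * w, cyt / h) * deficit / dsum
        else:
            ret = 0.0
        new_m = np.clip(m + h * (ret - k_rel * m), 0.0, crosslinks.m0)
        cyt -= float(new_m.sum() - m.sum())
        m = new_m
    crosslinks.m = m
    return cyt / FILGAP_COUNTS_PER_UM


def rebind_capacity(
    old: CrosslinkState, new_mesh: CellMesh, filgap_c: float
) -> tuple[CrosslinkState, float]:
    """Transfer crosslink bookkeeping across a retriangulation.

    Persisting corners keep (m, m0); corners of destroyed triangles
    surrender their bound molecules to the cytosol; corners of new triangles
    start empty with the global mean capacity.  The bound + cytosolic budget
    is conserved exactly.
    """
    new_keys = corner_keys(new_mesh)
    mean_m0 = float(old.m0.mean()) if old.m0.size else 0.0
    m = np.zeros(new_keys.shape)
    m0 = np.full(new_keys.shape, mean_m0)

    old_flat = old.keys.ravel()
    order = np.argsort(old_flat)
    srt = old_flat[order]
    new_flat = new_keys.ravel()
    pos = np.searchsorted(srt, new_flat)
    pos = np.clip(pos, 0, len(srt) - 1)
    hit = srt[pos] == new_flat if len(srt) else np.zeros(len(new_flat), bool)
    src = order[pos[hit]]
    m.ravel()[hit] = old.m.ravel()[src]
    m0.ravel()[hit] = old.m0.ravel()[src]

    surrendered = float(old.m.sum() - m.sum())
    filgap_c += surrendered / FILGAP_COUNTS_PER_UM
    return CrosslinkState(m=m, m0=m0, keys=new_keys), filgap_c
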