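"""Time-dependent protocols, the full right-hand side, and stiff integration.

Protocols are specified in minutes (the convention of the experiments the
model emulates); the integrator works in milliseconds with a single
conversion point.  Energy deprivation (ED) scales the Na+/K+-ATPase by a
smooth U-shaped waveform that drops to a floor ``P_min``; stimulation injects
a square-wave current into the neuronal Na+ equation; blockades multiply
pathway permeabilities by factors in [0, 1] inside scheduled windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import (I_CA_A, I_CA_N, I_CL_A, I_CL_N, I_D, I_GLU_A, I_GLU_N,
                   I_H, I_K_A, I_K_N, I_M, I_NA_A, I_NA_N, I_NGATE, I_R,
                   I_R1, I_R2, I_R3, I_N, I_WA, I_WN, NSTATE, STATE_NAMES,
                   SYNAPTIC_INDICES, ConservedTotals, Geometry,
                   InvalidStateError, PhysicalConstants, compartment_view,
                   osmotic_gradient)
from .glutamate import VesicleParams, pool_rhs
from .transport import (Blockade, Pathway, TransportParams, eaat_flux,
                        gate_rates, gated_currents, kcc_flux, kir_current,
                        leak_current, ncx_current, nka_current, nkcc1_flux)
from . import _fast
from ._fast import HAVE_NUMBA, NPAR, rhs_fast

log = logging.getLogger(__name__)

__all__ = [
    "EDProtocol",
    "StimulusProtocol",
    "BlockadeWindow",
    "Protocols",
    "SimulationResult",
    "SimulationError",
    "ed_waveform",
    "stimulus_current",
    "full_rhs",
    "rhs_autonomous",
    "integrate",
    "count_spikes",
    "observables",
]

MS_PER_MIN = 60_000.0
#: Eq-7-style waveforms are singular at P_min = 0; requests below this floor
#: are clamped (the pump is then off to within solver tolerance anyway).
P_MIN_FLOOR = 1e-6


class SimulationError(RuntimeError):
    """Integrator failure, carrying the last valid state for diagnosis."""

    def __init__(self, message: str, t_min: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.t_min = t_min
        self.last_state = last_state


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EDProtocol:
    """Transient energy deprivation: pump capacity drops smoothly to P_min.

    ``P_min`` is a fraction of baseline pump capacity (0, 1]; ``beta``
    controls the steepness of the onset/offset ramps (1/min; the default was
    identified so a 5-minute half-capacity deprivation is just survivable
    while a 15-minute one is not, the reference dichotomy); times in minutes.
    """

    P_min: float = 0.5
    t_start: float = 5.0
    t_end: float = 10.0
    beta: float = 1.7

    def __post_init__(self) -> None:
        if not (0.0 < self.P_min <= 1.0):
            if self.P_min <= 0.0:
                object.__setattr__(self, "P_min", P_MIN_FLOOR)
            else:
                raise ValueError("P_min must lie in (0, 1]")
        if self.P_min < P_MIN_FLOOR:
            object.__setattr__(self, "P_min", P_MIN_FLOOR)
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def ed_waveform(t_min: float, protocol: EDProtocol | None) -> float:
    """Available pump energy as a fraction of baseline at time ``t_min``.

    P_min + (1 - P_min) * I_block(t) where I_block is a pair of opposing
    sigmoids whose midpoints t1, t2 are shifted so the waveform crosses
    (1 + P_min)/2 exactly at t_start and t_end.
    """
    if protocol is None or protocol.P_min >= 1.0:
        return 1.0
    p = protocol.P_min
    # the half-crossing shift log(1/P_min - 1)/beta diverges as P_min -> 0;
    # below 5% the shift is held at its 5% value so the waveform keeps the
    # prescribed onset/offset times (the plateau still reaches P_min)
    shift = math.log(1.0 / max(p, 0.05) - 1.0) / protocol.beta
    t1 = protocol.t_start - shift
    t2 = protocol.t_end + shift
    b = protocol.beta

    def sig(x: float) -> float:
        if x > 500.0:
            return 0.0
        if x < -500.0:
            return 1.0
        return 1.0 / (1.0 + math.exp(x))

    i_block = sig(b * (t_min - t1)) + sig(-b * (t_min - t2))
    return min(p + (1.0 - p) * i_block, 1.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-wave current injected into the neuronal Na+ equation.

    ``amplitude`` pA, ``onset`` min, ``duration_s`` s; ``repeats`` pulses
    separated by ``interval`` minutes (onset to onset).
    """

    amplitude: float = 25.0
    onset: float = 5.0
    duration_s: float = 10.0
    repeats: int = 1
    interval: float = 2.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if self.duration_s <= 0 or self.repeats < 1:
            raise ValueError("invalid stimulus timing")

    def windows(self) -> list[tuple[float, float]]:
        d_min = self.duration_s / 60.0
        return [(self.onset + k * self.interval,
                 self.onset + k * self.interval + d_min)
                for k in range(self.repeats)]


def stimulus_current(t_min: float, protocol: StimulusProtocol | None) -> float:
    """I_stim(t) in pA: the amplitude inside active windows, else 0."""
    if protocol is None:
        return 0.0
    for t0, t1 in protocol.windows():
        if t0 <= t_min < t1:
            return protocol.amplitude
    return 0.0


@dataclass(frozen=True)
class BlockadeWindow:
    """Pathway blockade factors applied inside [t_on, t_off) minutes."""

    t_on: float
    t_off: float
    blockade: Blockade

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError("blockade window must have t_on < t_off")


@dataclass
class Protocols:
    """Scenario container: ED waveform, stimulation, blockade schedule.

    ``constant_energy`` (if set) overrides the ED waveform with a fixed pump
    fraction — used for equilibrium continuation and zero-energy limits, and
    may exceed 1.  ``clamp_synaptic`` freezes the Ca2+/glutamate sub-system
    (amounts, pools and their transport pathways) for Gibbs-Donnan runs.
    """

    ed: EDProtocol | None = None
    stim: StimulusProtocol | None = None
    blockades: tuple[BlockadeWindow, ...] = ()
    constant_energy: float | None = None
    clamp_synaptic: bool = False

    def energy(self, t_min: float) -> float:
        if self.constant_energy is not None:
            return self.constant_energy
        return ed_waveform(t_min, self.ed)

    def blockade_at(self, t_min: float) -> Blockade | None:
        active: dict = {}
        for w in self.blockades:
            if w.t_on <= t_min < w.t_off:
                for p, f in w.blockade.factors.items():
                    active[p] = min(active.get(p, 1.0), f)
        return Blockade(active) if active else None

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Times (min) where the protocol switches discontinuously."""
        pts = set()
        if self.stim is not None:
            for a, b in self.stim.windows():
                pts.update((a, b))
        for w in self.blockades:
            pts.update((w.t_on, w.t_off))
        return sorted(p for p in pts if t0 < p < t1)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def full_rhs(t_ms: float, y: np.ndarray, totals: ConservedTotals,
             geom: Geometry, consts: PhysicalConstants, tp: TransportParams,
             vp: VesicleParams, protocols: Protocols,
             blockade: Blockade | None = None) -> np.ndarray:
    """d/dt of the 21 state variables at time ``t_ms``.

    Assembles the per-species current sums with their 1/(z F) factors, the
    gate and vesicle-pool kinetics and the osmotic volume equations; blockade
    factors multiply the corresponding pathway permeabilities.
    """
    t_min = t_ms / MS_PER_MIN
    bl = blockade if blockade is not None else protocols.blockade_at(t_min)
    energy = protocols.energy(t_min)
    i_stim = stimulus_current(t_min, protocols.stim)
    return _rhs_core(y, totals, geom, consts, tp, vp, energy, i_stim, bl,
                     protocols.clamp_synaptic)


def rhs_autonomous(y: np.ndarray, totals: ConservedTotals, geom: Geometry,
                   consts: PhysicalConstants, tp: TransportParams,
                   vp: VesicleParams, energy: float = 1.0,
                   blockade: Blockade | None = None,
                   clamp_synaptic: bool = False) -> np.ndarray:
    """RHS at fixed pump energy, no stimulus — the autonomous vector field
    used by calibration and equilibrium continuation."""
    return _rhs_core(y, totals, geom, consts, tp, vp, energy, 0.0, blockade,
                     clamp_synaptic)


def _rhs_core(y, totals, geom, consts, tp, vp, energy, i_stim, bl,
              clamp_synaptic) -> np.ndarray:
    view = compartment_view(y, totals, geom, consts)
    F = consts.F
    dy = np.zeros(NSTATE)

    m, h, n_gate = y[I_M], y[I_H], y[I_NGATE]
    ig_na, ig_k, ig_cl, ig_ca = gated_currents(view, m, h, n_gate, tp, consts, bl)
    i_nka_n = nka_current(view, tp, consts, energy, "n", bl)
    j_kcc = kcc_flux(view, tp, consts, bl)
    il_na_n = leak_current(view, tp, consts, "Na", "n", bl)
    il_k_n = leak_current(view, tp, consts, "K", "n", bl)
    il_cl_n = leak_current(view, tp, consts, "Cl", "n", bl)

    i_nka_a = nka_current(view, tp, consts, energy, "a", bl)
    i_kir = kir_current(view, tp, consts, bl)
    j_nkcc1 = nkcc1_flux(view, tp, consts, bl)
    il_na_a = leak_current(view, tp, consts, "Na", "a", bl)
    il_k_a = leak_current(view, tp, consts, "K", "a", bl)
    il_cl_a = leak_current(view, tp, consts, "Cl", "a", bl)

    if clamp_synaptic:
        i_ncx_n = i_ncx_a = 0.0
        j_eaat_n = j_eaat_a = 0.0
        ig_ca = 0.0
        il_ca_n = il_ca_a = il_glu_n = il_glu_a = 0.0
    else:
        i_ncx_n = ncx_current(view, tp, consts, "n", bl)
        i_ncx_a = ncx_current(view, tp, consts, "a", bl)
        j_eaat_n = eaat_flux(view, tp, consts, "n", bl)
        j_eaat_a = eaat_flux(view, tp, consts, "a", bl)
        il_ca_n = leak_current(view, tp, consts, "Ca", "n", bl)
        il_ca_a = leak_current(view, tp, consts, "Ca", "a", bl)
        il_glu_n = leak_current(view, tp, consts, "Glu", "n", bl)
        il_glu_a = leak_current(view, tp, consts, "Glu", "a", bl)

    # neuron: dN = -sum(I)/zF (+ molar cotransporter fluxes, + stimulus)
    dy[I_NA_N] = (-(ig_na + 3.0 * i_nka_n + 3.0 * i_ncx_n + il_na_n) / F
                  + 3.0 * j_eaat_n + i_stim / F)
    dy[I_K_N] = (-(ig_k - 2.0 * i_nka_n + il_k_n) / F - j_eaat_n + j_kcc)
    dy[I_CL_N] = (ig_cl + il_cl_n) / F + j_kcc
    dy[I_CA_N] = -(ig_ca - i_ncx_n + il_ca_n) / (2.0 * F)

    # astrocyte
    dy[I_NA_A] = (-(3.0 * i_nka_a + 3.0 * i_ncx_a + il_na_a) / F
                  + 3.0 * j_eaat_a + j_nkcc1)
    dy[I_K_A] = (-(-2.0 * i_nka_a + i_kir + il_k_a) / F - j_eaat_a + j_nkcc1)
    dy[I_CL_A] = il_cl_a / F + 2.0 * j_nkcc1
    dy[I_CA_A] = -(-i_ncx_a + il_ca_a) / (2.0 * F)
    dy[I_GLU_A] = j_eaat_a + il_glu_a / F

    # Hodgkin-Huxley gates
    a_m, b_m, a_h, b_h, a_n, b_n = gate_rates(view.V_n)
    dy[I_M] = a_m * (1.0 - m) - b_m * m
    dy[I_H] = a_h * (1.0 - h) - b_h * h
    dy[I_NGATE] = a_n * (1.0 - n_gate) - b_n * n_gate

    # vesicle cycle (neuronal glutamate N_I is the inactive pool)
    glu_uptake = j_eaat_n + il_glu_n / F
    d_i, d_d, d_n, d_r, d_r1, d_r2, d_r3 = pool_rhs(
        y[I_GLU_N], y[I_D], y[I_N], y[I_R], y[I_R1], y[I_R2], y[I_R3],
        view.ca_n, vp, glu_uptake)
    dy[I_GLU_N] = d_i
    dy[I_D], dy[I_N], dy[I_R] = d_d, d_n, d_r
    dy[I_R1], dy[I_R2], dy[I_R3] = d_r1, d_r2, d_r3

    # osmotic volume dynamics
    dy[I_WN] = tp.L_H2O_n * osmotic_gradient(view, totals, consts, "n")
    dy[I_WA] = tp.L_H2O_a * osmotic_gradient(view, totals, consts, "a")

    if clamp_synaptic:
        for i in SYNAPTIC_INDICES:
            dy[i] = 0.0
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise InvalidStateError(f"non-finite derivative for {bad}")
    return dy


# ---------------------------------------------------------------------------
# compiled fast path (parameter packing for trisyn._fast.rhs_fast)
# ---------------------------------------------------------------------------

_BLOCK_SLOTS = (
    (_fast.J_B_GNA, Pathway.GATED_NA_N), (_fast.J_B_GK, Pathway.GATED_K_N),
    (_fast.J_B_GCL, Pathway.GATED_CL_N), (_fast.J_B_GCA, Pathway.GATED_CA_N),
    (_fast.J_B_NKA_N, Pathway.NKA_N), (_fast.J_B_KCC, Pathway.KCC_N),
    (_fast.J_B_NCX_N, Pathway.NCX_N), (_fast.J_B_EAAT_N, Pathway.EAAT_N),
    (_fast.J_B_LEAK_N, Pathway.LEAK_N), (_fast.J_B_NKA_A, Pathway.NKA_A),
    (_fast.J_B_KIR, Pathway.KIR_A), (_fast.J_B_NKCC1, Pathway.NKCC1_A),
    (_fast.J_B_NCX_A, Pathway.NCX_A), (_fast.J_B_EAAT_A, Pathway.EAAT_A),
    (_fast.J_B_LEAK_A, Pathway.LEAK_A),
)


def pack_params(model, energy_mode: int = 0, energy_val: float = 1.0,
                ed: EDProtocol | None = None, i_stim: float = 0.0,
                blockade: Blockade | None = None,
                clamp_synaptic: bool = False) -> np.ndarray:
    """Flatten model + protocol-segment constants for the compiled RHS."""
    c, t, tp, vp = model.consts, model.totals, model.tp, model.vp
    P = np.empty(NPAR)
    P[_fast.J_F] = c.F
    P[_fast.J_RTF] = c.rtf
    P[_fast.J_RT] = c.R * c.T
    P[_fast.J_C_N] = c.C_n
    P[_fast.J_C_A] = c.C_a
    P[_fast.J_W_PS] = c.W_ps
    P[_fast.J_W_C] = c.W_c
    P[_fast.J_W_PAP] = c.W_pap
    P[_fast.J_C_NA] = t.C_Na
    P[_fast.J_C_K] = t.C_K
    P[_fast.J_C_CL] = t.C_Cl
    P[_fast.J_C_CA] = t.C_Ca
    P[_fast.J_C_GLU] = t.C_Glu
    P[_fast.J_C_W] = t.C_W
    P[_fast.J_NA_N_IMP] = t.N_A_n
    P[_fast.J_NA_A_IMP] = t.N_A_a
    P[_fast.J_NA_E_IMP] = t.N_A_e
    P[_fast.J_NB_A_IMP] = t.N_B_a
    P[_fast.J_NB_E_IMP] = t.N_B_e
    P[_fast.J_PG_NA] = tp.P_G_Na_n
    P[_fast.J_PG_K] = tp.P_G_K_n
    P[_fast.J_PG_CL] = tp.P_G_Cl_n
    P[_fast.J_PG_CA] = tp.P_G_Ca_n
    P[_fast.J_CA_VH] = tp.ca_act_vhalf
    P[_fast.J_CA_SL] = tp.ca_act_slope
    P[_fast.J_CA_PW] = float(tp.ca_act_power)
    P[_fast.J_PNKA_N] = tp.P_NKA_n
    P[_fast.J_PNKA_A] = tp.P_NKA_a
    P[_fast.J_ANKA_NA] = tp.alpha_NKA_Na
    P[_fast.J_ANKA_K] = tp.alpha_NKA_K
    P[_fast.J_PSCALE] = tp.P_scale
    P[_fast.J_PKCL] = tp.P_KCl_n
    P[_fast.J_PKIR] = tp.P_Kir_a
    P[_fast.J_PNKCC1] = tp.P_NKCC1_a
    P[_fast.J_PNCX_N] = tp.P_NCX_n
    P[_fast.J_PNCX_A] = tp.P_NCX_a
    P[_fast.J_ANCX_NA] = tp.alpha_NCX_Na
    P[_fast.J_ANCX_CA] = tp.alpha_NCX_Ca
    P[_fast.J_ETA] = tp.eta_NCX
    P[_fast.J_KNCX] = tp.k_NCX
    P[_fast.J_PEAAT_N] = tp.P_EAAT_n
    P[_fast.J_PEAAT_A] = tp.P_EAAT_a
    P[_fast.J_AH_N] = tp.alpha_H_n
    P[_fast.J_AH_A] = tp.alpha_H_a
    P[_fast.J_LN] = tp.L_H2O_n
    P[_fast.J_LA] = tp.L_H2O_a
    P[_fast.J_PL_NA_N] = tp.P_L_Na_n
    P[_fast.J_PL_K_N] = tp.P_L_K_n
    P[_fast.J_PL_CL_N] = tp.P_L_Cl_n
    P[_fast.J_PL_CA_N] = tp.P_L_Ca_n
    P[_fast.J_PL_GLU_N] = tp.P_L_Glu_n
    P[_fast.J_PL_NA_A] = tp.P_L_Na_a
    P[_fast.J_PL_K_A] = tp.P_L_K_a
    P[_fast.J_PL_CL_A] = tp.P_L_Cl_a
    P[_fast.J_PL_CA_A] = tp.P_L_Ca_a
    P[_fast.J_PL_GLU_A] = tp.P_L_Glu_a
    P[_fast.J_K1MAX] = vp.k1_max
    P[_fast.J_KM] = vp.K_M
    P[_fast.J_KDV] = vp.K_Dv
    P[_fast.J_K20] = vp.k20
    P[_fast.J_K2CAT] = vp.k2_cat
    P[_fast.J_KM20] = vp.k_m20
    P[_fast.J_KM2CAT] = 0.0 if math.isnan(vp.k_m2cat) else vp.k_m2cat
    P[_fast.J_KM1] = vp.k_m1
    P[_fast.J_K3] = vp.k3
    P[_fast.J_KM3] = vp.k_m3
    P[_fast.J_K4] = vp.k4
    P[_fast.J_TAU] = vp.tau_rec
    if energy_mode == 1 and ed is not None and ed.P_min < 1.0:
        shift = math.log(1.0 / max(ed.P_min, 0.05) - 1.0) / ed.beta
        P[_fast.J_EMODE] = 1.0
        P[_fast.J_EVAL] = ed.P_min
        P[_fast.J_ET1] = ed.t_start - shift
        P[_fast.J_ET2] = ed.t_end + shift
        P[_fast.J_EBETA] = ed.beta
    else:
        P[_fast.J_EMODE] = 0.0
        P[_fast.J_EVAL] = energy_val
        P[_fast.J_ET1] = P[_fast.J_ET2] = P[_fast.J_EBETA] = 0.0
    P[_fast.J_ISTIM] = i_stim
    P[_fast.J_CLAMP] = 1.0 if clamp_synaptic else 0.0
    P[_fast.J_NKA_FORM] = 0.0 if tp.nka_g_form == "saturating" else 1.0
    bl = blockade or Blockade()
    for slot, pw in _BLOCK_SLOTS:
        P[slot] = bl.factor(pw)
    return P


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory plus derived time series and run metadata.

    ``t`` is in minutes, ``y`` has one row per state; ``series`` holds the
    derived observables (potentials mV, concentrations mM, volumes).
    """

    t: np.ndarray
    y: np.ndarray
    series: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {"t_min": self.t}
        data.update(self.series)
        return pd.DataFrame(data)


def _derive_series(t_min, y, model) -> dict:
    totals, consts, geom = model.totals, model.consts, model.geom
    F = consts.F
    w_n, w_a = y[I_WN], y[I_WA]
    w_e = totals.C_W - w_n - w_a
    v_n = F / consts.C_n * (y[I_NA_N] + y[I_K_N] - y[I_CL_N]
                            + 2 * y[I_CA_N] - y[I_GLU_N] - totals.N_A_n)
    v_a = F / consts.C_a * (y[I_NA_A] + y[I_K_A] - y[I_CL_A]
                            + 2 * y[I_CA_A] - y[I_GLU_A]
                            - totals.N_A_a + totals.N_B_a)
    pool_sum = (y[I_GLU_N] + y[I_D] + y[I_N] + y[I_R] + y[I_R1] + y[I_R2]
                + y[I_R3] + y[I_GLU_A])
    n_f = np.clip(totals.C_Glu - pool_sum, 0.0, None)
    return {
        "V_n": v_n, "V_a": v_a,
        "Na_n": y[I_NA_N] / w_n, "K_n": y[I_K_N] / w_n, "Cl_n": y[I_CL_N] / w_n,
        "Na_a": y[I_NA_A] / w_a, "K_a": y[I_K_A] / w_a, "Cl_a": y[I_CL_A] / w_a,
        "Na_e": (totals.C_Na - y[I_NA_N] - y[I_NA_A]) / w_e,
        "K_e": (totals.C_K - y[I_K_N] - y[I_K_A]) / w_e,
        "Cl_e": (totals.C_Cl - y[I_CL_N] - y[I_CL_A]) / w_e,
        "Ca_n": y[I_CA_N] / consts.W_ps,
        "Ca_c": (totals.C_Ca - y[I_CA_N] - y[I_CA_A]) / consts.W_c,
        "Glu_c": n_f / consts.W_c,
        "W_n": w_n, "W_a": w_a, "W_e": w_e,
    }


def default_atol(y0: np.ndarray) -> np.ndarray:
    """Per-state absolute tolerance scaled to baseline magnitudes (the state
    spans ~13 orders of magnitude, from fmol-scale ions to the smallest
    vesicle pool)."""
    return np.maximum(np.abs(y0) * 1e-10, 1e-20)


def integrate(model, protocols: Protocols | None = None, t_end: float = 60.0,
              t_start: float = 0.0, y0: np.ndarray | None = None,
              rtol: float = 1e-8, atol=None, coarse_dt_ms: float = 250.0,
              stim_dt_ms: float = 0.1, method: str = "LSODA") -> SimulationResult:
    """Integrate the model over [t_start, t_end] minutes.

    The time span is split at protocol discontinuities (stimulus and blockade
    edges) and the solver restarted at each; output is sampled densely
    (``stim_dt_ms``, default 0.1 ms = 10 samples/ms) inside stimulation
    windows and coarsely elsewhere.
    """
    protocols = protocols or Protocols()
    y = (model.y0 if y0 is None else np.asarray(y0, float)).copy()
    if atol is None:
        atol = default_atol(model.y0)

    edges = [t_start] + protocols.breakpoints(t_start, t_end) + [t_end]
    stim_windows = protocols.stim.windows() if protocols.stim else []

    def in_stim(a: float, b: float) -> bool:
        mid = 0.5 * (a + b)
        return any(w0 <= mid < w1 for w0, w1 in stim_windows)

    ts, ys = [], []
    nfev = 0
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a <= 0:
            continue
        mid = 0.5 * (a + b)
        bl = protocols.blockade_at(mid if in_stim(a, b) else
                                   a + 1e-9 * max(1.0, abs(a)))
        dt = stim_dt_ms if in_stim(a, b) else coarse_dt_ms
        t_eval = np.arange(a * MS_PER_MIN, b * MS_PER_MIN, dt)
        if len(t_eval) == 0 or t_eval[-1] < b * MS_PER_MIN:
            t_eval = np.append(t_eval, b * MS_PER_MIN)

        if HAVE_NUMBA:
            # stimulus and blockade are constant within a segment; the ED
            # waveform is evaluated inside the compiled RHS
            if protocols.constant_energy is not None:
                P = pack_params(model, 0, protocols.constant_energy, None,
                                stimulus_current(mid, protocols.stim), bl,
                                protocols.clamp_synaptic)
            else:
                P = pack_params(model, 1, 1.0, protocols.ed,
                                stimulus_current(mid, protocols.stim), bl,
                                protocols.clamp_synaptic)

            def f(t_ms, yy, _P=P):
                return rhs_fast(t_ms, yy, _P)
        else:  # pragma: no cover - reference fallback
            def f(t_ms, yy, _bl=bl):
                return full_rhs(t_ms, yy, model.totals, model.geom,
                                model.consts, model.tp, model.vp, protocols,
                                blockade=_bl)

        sol = solve_ivp(f, (a * MS_PER_MIN, b * MS_PER_MIN), y, method=method,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        nfev += sol.nfev
        if not sol.success:
            raise SimulationError(
                f"solver failed at t = {sol.t[-1] / MS_PER_MIN:.3f} min: "
                f"{sol.message}",
                t_min=sol.t[-1] / MS_PER_MIN,
                last_state=sol.y[:, -1] if sol.y.size else y)
        if ts:
            ts.append(sol.t[1:])
            ys.append(sol.y[:, 1:])
        else:
            ts.append(sol.t)
            ys.append(sol.y)
        y = sol.y[:, -1].copy()
        log.info("segment [%.2f, %.2f] min done (%d steps)", a, b, sol.t.size)

    t_ms = np.concatenate(ts)
    yy = np.concatenate(ys, axis=1)
    t_min = t_ms / MS_PER_MIN
    series = _derive_series(t_min, yy, model)
    events = []
    if protocols.ed is not None:
        events.append(("ed_start", protocols.ed.t_start))
        events.append(("ed_end", protocols.ed.t_end))
    for w0, w1 in stim_windows:
        events.append(("stim_on", w0))
        events.append(("stim_off", w1))
    for w in protocols.blockades:
        events.append(("block_on", w.t_on))
        events.append(("block_off", w.t_off))
    return SimulationResult(t=t_min, y=yy, series=series,
                            events=sorted(events, key=lambda e: e[1]),
                            stats={"nfev": nfev, "n_out": t_min.size})


# ---------------------------------------------------------------------------
# derived observables
# ---------------------------------------------------------------------------

def count_spikes(t_ms: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                 refractory_ms: float = 2.0) -> int:
    """Action potentials as upward threshold crossings with a refractory gap.

    Warns if the trace is sampled more coarsely than ~2 samples/ms (spikes
    could be missed).
    """
    t_ms = np.asarray(t_ms, float)
    v = np.asarray(v, float)
    if t_ms.size > 1:
        dt = np.median(np.diff(t_ms))
        if dt > 0.5:
            log.warning("spike counting on a trace sampled every %.2f ms; "
                        "counts may be unreliable", dt)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if up.size == 0:
        return 0
    count, t_last = 1, t_ms[up[0]]
    for i in up[1:]:
        if t_ms[i] - t_last >= refractory_ms:
            count += 1
            t_last = t_ms[i]
    return count


def observables(result: SimulationResult, model,
                protocols: Protocols | None = None,
                recovery_tol_mv: float = 2.0) -> dict:
    """Summary metrics of a finished run.

    Relative volume changes are against the baseline volumes; the recovery
    flag tests the final neuronal potential against baseline (callers should
    run >= 30 min past energy restoration for it to be meaningful); glutamate
    transients are peak relative cleft-glutamate changes per stimulation
    window, against the value at the window start.
    """
    s = result.series
    w_n0, w_a0 = model.geom.W_n0, model.geom.W_a0
    v_n0 = model.baseline.V_n0
    v_a0 = model.baseline.V_a0
    out = {
        "V_n_final": float(s["V_n"][-1]),
        "V_a_final": float(s["V_a"][-1]),
        "peak_dWn_pct": float(np.max(np.abs(s["W_n"] - w_n0)) / w_n0 * 100),
        "peak_dWa_pct": float(np.max(np.abs(s["W_a"] - w_a0)) / w_a0 * 100),
        "final_dWn_pct": float((s["W_n"][-1] - w_n0) / w_n0 * 100),
        "final_dWa_pct": float((s["W_a"][-1] - w_a0) / w_a0 * 100),
        "recovered": bool(abs(s["V_n"][-1] - v_n0) < recovery_tol_mv
                          and abs(s["V_a"][-1] - v_a0) < recovery_tol_mv),
    }
    stim = protocols.stim if protocols else None
    if stim is not None:
        t_ms = result.t * MS_PER_MIN
        spikes, transients = [], []
        for w0, w1 in stim.windows():
            sel = (result.t >= w0) & (result.t <= w1 + 5.0 / 60.0)
            if not np.any(sel):
                continue
            spikes.append(count_spikes(t_ms[sel], s["V_n"][sel]))
            glu = s["Glu_c"][sel]
            ref = glu[0] if glu[0] > 0 else model.baseline.glu_c0
            transients.append(float(np.max(np.abs(glu - ref)) / ref * 100))
        out["spike_counts"] = spikes
        out["glu_transient_pct"] = transients
    return out
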