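"""Baseline calibration: everything the model derives rather than tabulates.

Given the baseline ("resting") concentrations, potentials and geometry, this
module computes, in order:

1. conserved totals C_X and the impermeant-ion amounts (from the osmotic rest
   conditions, the two capacitor relations and global electroneutrality);
2. the Ca2+-catalysed vesicle un-priming rate k_-2^cat, from stationarity of
   the baseline vesicle-pool occupancies (its value is not independently
   known; the baseline pool distribution pins it);
3. the ten leak permeabilities P_L^{X,i}, by zeroing each species' amount
   equation at the baseline state.

After calibration the baseline state is an equilibrium of the full 21-state
system to ~1e-12 fmol/ms, for any pump scaling P_scale (the leaks absorb the
scaled pump flux).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .core import (I_M, I_H, I_NGATE, NSTATE, STATE_NAMES, CalibrationError,
                   ConservedTotals, Geometry, ModelState, PhysicalConstants)
from .glutamate import VesicleParams, vesicle_rates
from .transport import TransportParams, gate_steady_state

log = logging.getLogger(__name__)

__all__ = [
    "BaselineSpec",
    "Model",
    "calibrate",
    "conserved_totals",
    "estimate_impermeants",
    "estimate_leak_permeabilities",
    "recalibrate_for_pscale",
    "init_glutamate_pools",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline (resting) conditions from which everything else is derived.

    Intracellular values are literature values for cortical neurons and
    astrocytes; the extracellular side is a standard CSF-like composition
    chosen to close the osmotic and charge budgets.  Concentrations in mM,
    potentials in mV, pool amounts in fmol.
    """

    V_n0: float = -65.5
    V_a0: float = -80.0
    na_n0: float = 13.0
    k_n0: float = 145.0
    cl_n0: float = 7.0
    ca_n0: float = 1e-4
    glu_n0: float = 2.2385
    na_a0: float = 13.0
    k_a0: float = 80.0
    cl_a0: float = 35.0
    ca_a0: float = 1e-4
    glu_a0: float = 2.0
    na_e0: float = 152.0
    k_e0: float = 3.0
    cl_e0: float = 135.0
    ca_c0: float = 1.8
    glu_c0: float = 1e-4
    # baseline vesicle-pool amounts (fmol); N_I follows from glu_n0 * W_ps
    N_D0: float = 4.04605e-7
    N_N0: float = 3.36567e-4
    N_R0: float = 4.14849e-4
    N_R10: float = 9.778061e-6
    N_R20: float = 7.655809e-8
    N_R30: float = 2.08192593e-11

    def __post_init__(self) -> None:
        for name in ("na_n0", "k_n0", "cl_n0", "glu_n0", "na_a0", "k_a0",
                     "cl_a0", "glu_a0", "na_e0", "k_e0", "cl_e0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isfinite(self.V_n0) or not math.isfinite(self.V_a0):
            raise ValueError("baseline potentials must be finite")

    def copy(self, **changes) -> "BaselineSpec":
        return replace(self, **changes)


@dataclass
class Model:
    """A calibrated model: parameters, conserved totals and baseline state."""

    consts: PhysicalConstants
    geom: Geometry
    baseline: BaselineSpec
    totals: ConservedTotals
    tp: TransportParams
    vp: VesicleParams
    y0: np.ndarray
    report: dict = field(default_factory=dict)

    @property
    def baseline_state(self) -> ModelState:
        return ModelState.from_array(self.y0)

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# impermeant ions and conserved totals
# ---------------------------------------------------------------------------

def _neuron_mobile_charge(b: BaselineSpec, geom: Geometry,
                          consts: PhysicalConstants) -> float:
    return (b.na_n0 * geom.W_n0 + b.k_n0 * geom.W_n0 - b.cl_n0 * geom.W_n0
            + 2.0 * b.ca_n0 * consts.W_ps - b.glu_n0 * consts.W_ps)


def _astro_mobile_charge(b: BaselineSpec, geom: Geometry,
                         consts: PhysicalConstants) -> float:
    return (b.na_a0 * geom.W_a0 + b.k_a0 * geom.W_a0 - b.cl_a0 * geom.W_a0
            + 2.0 * b.ca_a0 * consts.W_pap - b.glu_a0 * consts.W_pap)


def estimate_impermeants(baseline: BaselineSpec, consts: PhysicalConstants,
                         geom: Geometry) -> tuple[float, float, float, float, float]:
    """Impermeant amounts (N_A_n, N_A_a, N_A_e, N_B_a, N_B_e) in fmol.

    Solves the five linear rest conditions: the two capacitor relations
    V_i = (F/C_i) sum z_X N_X^i, osmotic balance of each soma against the
    extracellular space, and global electroneutrality.  The neuron carries
    impermeant anions only.
    """
    F = consts.F
    q_n = consts.C_n * baseline.V_n0 / F
    q_a = consts.C_a * baseline.V_a0 / F
    # capacitor relations
    n_a_n = _neuron_mobile_charge(baseline, geom, consts) - q_n
    diff_a = _astro_mobile_charge(baseline, geom, consts) - q_a  # N_A_a - N_B_a
    # osmotic balance, neuron vs ECS, fixes the total ECS impermeant conc.
    osm_e_mobile = baseline.na_e0 + baseline.k_e0 + baseline.cl_e0
    osm_n = (baseline.na_n0 + baseline.k_n0 + baseline.cl_n0
             + n_a_n / geom.W_n0)
    sum_e = geom.W_e0 * (osm_n - osm_e_mobile)  # N_A_e + N_B_e
    # osmotic balance, astrocyte vs ECS
    sum_a = geom.W_a0 * (osm_e_mobile + sum_e / geom.W_e0
                         - (baseline.na_a0 + baseline.k_a0 + baseline.cl_a0))
    # global electroneutrality fixes the ECS split
    mob = _mobile_totals(baseline, geom, consts)
    mobile_charge = mob["C_Na"] + mob["C_K"] - mob["C_Cl"] + 2 * mob["C_Ca"] - mob["C_Glu"]
    diff_e = -mobile_charge + n_a_n + (sum_a + diff_a) / 2.0 - (sum_a - diff_a) / 2.0
    # diff_e = N_B_e - N_A_e ; note (A_a - B_a) == diff_a was already used
    n_a_a = (sum_a + diff_a) / 2.0
    n_b_a = (sum_a - diff_a) / 2.0
    n_b_e = (sum_e + diff_e) / 2.0
    n_a_e = (sum_e - diff_e) / 2.0
    for name, v in (("N_A_n", n_a_n), ("N_A_a", n_a_a), ("N_A_e", n_a_e),
                    ("N_B_a", n_b_a), ("N_B_e", n_b_e)):
        if not math.isfinite(v):
            raise CalibrationError(f"impermeant estimation produced {name}={v}")
        if v < -1e-9:
            raise CalibrationError(
                f"impermeant estimation infeasible: {name} = {v:.4f} fmol < 0")
    return n_a_n, n_a_a, n_a_e, n_b_a, n_b_e


def _mobile_totals(b: BaselineSpec, geom: Geometry,
                   consts: PhysicalConstants) -> dict:
    n_i0 = b.glu_n0 * consts.W_ps
    pool_sum = (n_i0 + b.N_D0 + b.N_N0 + b.N_R0 + b.N_R10 + b.N_R20 + b.N_R30)
    return {
        "C_Na": b.na_n0 * geom.W_n0 + b.na_a0 * geom.W_a0 + b.na_e0 * geom.W_e0,
        "C_K": b.k_n0 * geom.W_n0 + b.k_a0 * geom.W_a0 + b.k_e0 * geom.W_e0,
        "C_Cl": b.cl_n0 * geom.W_n0 + b.cl_a0 * geom.W_a0 + b.cl_e0 * geom.W_e0,
        "C_Ca": b.ca_n0 * consts.W_ps + b.ca_a0 * consts.W_pap + b.ca_c0 * consts.W_c,
        "C_Glu": pool_sum + b.glu_a0 * consts.W_pap + b.glu_c0 * consts.W_c,
    }


def conserved_totals(baseline: BaselineSpec, geom: Geometry,
                     consts: PhysicalConstants,
                     impermeants: tuple | None = None) -> ConservedTotals:
    """Conserved totals C_X (summed over every compartment) and C_W = W_tot."""
    if impermeants is None:
        impermeants = estimate_impermeants(baseline, consts, geom)
    n_a_n, n_a_a, n_a_e, n_b_a, n_b_e = impermeants
    mob = _mobile_totals(baseline, geom, consts)
    return ConservedTotals(C_W=geom.W_tot, N_A_n=n_a_n, N_A_a=n_a_a,
                           N_A_e=n_a_e, N_B_a=n_b_a, N_B_e=n_b_e, **mob)


def initial_state(baseline: BaselineSpec, geom: Geometry,
                  consts: PhysicalConstants) -> np.ndarray:
    """Baseline state vector: amounts from concentrations, gates at their
    steady state for V_n0, vesicle pools verbatim."""
    m0, h0, n0 = gate_steady_state(baseline.V_n0)
    vals = {
        "N_Na_n": baseline.na_n0 * geom.W_n0,
        "N_K_n": baseline.k_n0 * geom.W_n0,
        "N_Cl_n": baseline.cl_n0 * geom.W_n0,
        "N_Ca_n": baseline.ca_n0 * consts.W_ps,
        "N_Glu_n": baseline.glu_n0 * consts.W_ps,
        "N_Na_a": baseline.na_a0 * geom.W_a0,
        "N_K_a": baseline.k_a0 * geom.W_a0,
        "N_Cl_a": baseline.cl_a0 * geom.W_a0,
        "N_Ca_a": baseline.ca_a0 * consts.W_pap,
        "N_Glu_a": baseline.glu_a0 * consts.W_pap,
        "m": m0, "h": h0, "n_gate": n0,
        "N_D": baseline.N_D0, "N_N": baseline.N_N0, "N_R": baseline.N_R0,
        "N_R1": baseline.N_R10, "N_R2": baseline.N_R20, "N_R3": baseline.N_R30,
        "W_n": geom.W_n0, "W_a": geom.W_a0,
    }
    return np.array([vals[n] for n in STATE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# vesicle-cycle closure
# ---------------------------------------------------------------------------

def calibrate_vesicle_backrate(baseline: BaselineSpec,
                               vp: VesicleParams) -> float:
    """Ca2+-catalysed un-priming rate k_-2^cat (ms^-1) from pool stationarity.

    Requires d/dt N_R = 0 at the baseline Ca2+ concentration with the
    baseline pool occupancies:
    k_-2 = (k2 N_N + k_-3 N_R1)/N_R - 3 k3 [Ca], then
    k_-2^cat = (k_-2 - k_-20)/g([Ca]).
    """
    ca = baseline.ca_n0
    probe = vp.copy(k_m2cat=0.0)
    _, k2, _ = vesicle_rates(ca, probe)
    k_m2 = ((k2 * baseline.N_N0 + vp.k_m3 * baseline.N_R10) / baseline.N_R0
            - 3.0 * vp.k3 * ca)
    g = ca / (ca + vp.K_Dv)
    k_m2cat = (k_m2 - vp.k_m20) / g
    if k_m2cat < 0:
        raise CalibrationError("vesicle back-rate calibration gave k_-2^cat < 0")
    return k_m2cat


def init_glutamate_pools(baseline: BaselineSpec, vp: VesicleParams,
                         consts: PhysicalConstants,
                         mode: str = "table") -> dict:
    """Baseline vesicle-pool amounts (fmol).

    ``table`` (default) returns the configured baseline occupancies.
    ``steady_state`` re-derives them as the null vector of the linearised
    chain at baseline Ca2+ (the chain is linear in the pools once N_I is
    fixed), scaled to the configured total vesicular glutamate.
    """
    names = ("N_D", "N_N", "N_R", "N_R1", "N_R2", "N_R3")
    table = {"N_D": baseline.N_D0, "N_N": baseline.N_N0, "N_R": baseline.N_R0,
             "N_R1": baseline.N_R10, "N_R2": baseline.N_R20,
             "N_R3": baseline.N_R30}
    if mode == "table":
        return table
    if mode != "steady_state":
        raise ValueError("mode must be 'table' or 'steady_state'")
    ca = baseline.ca_n0
    n_i = baseline.glu_n0 * consts.W_ps
    k1, k2, k_m2 = vesicle_rates(ca, vp)
    k3ca = vp.k3 * ca
    a = np.zeros((6, 6))
    # rows: dD, dN, dR, dR1, dR2, dR3 as linear forms in (D, N, R, R1, R2, R3)
    a[0, 0] = n_i / vp.tau_rec - k1
    a[0, 1] = vp.k_m1
    a[1, 0] = k1
    a[1, 1] = -(vp.k_m1 + k2)
    a[1, 2] = k_m2
    a[2, 1] = k2
    a[2, 2] = -(k_m2 + 3 * k3ca)
    a[2, 3] = vp.k_m3
    a[3, 2] = 3 * k3ca
    a[3, 3] = -(vp.k_m3 + 2 * k3ca)
    a[3, 4] = 2 * vp.k_m3
    a[4, 3] = 2 * k3ca
    a[4, 4] = -(2 * vp.k_m3 + k3ca)
    a[4, 5] = 3 * vp.k_m3
    a[5, 4] = k3ca
    a[5, 5] = -(3 * vp.k_m3 + vp.k4)
    _, s, vt = np.linalg.svd(a)
    v = vt[-1]
    if s[-1] > 1e-6 * s[0]:
        raise CalibrationError(
            "vesicle chain has no steady state at this Ca2+ (null space empty); "
            "calibrate k_-2^cat first")
    if np.all(v <= 0):
        v = -v
    if np.any(v < -1e-12 * np.max(np.abs(v))):
        raise CalibrationError("vesicle steady state is not non-negative")
    v = np.clip(v, 0.0, None)
    v *= sum(table.values()) / v.sum()
    return dict(zip(names, v.tolist()))


# ---------------------------------------------------------------------------
# leak permeabilities
# ---------------------------------------------------------------------------

_LEAK_TO_STATE = {
    "P_L_Na_n": "N_Na_n", "P_L_K_n": "N_K_n", "P_L_Cl_n": "N_Cl_n",
    "P_L_Ca_n": "N_Ca_n", "P_L_Glu_n": "N_Glu_n",
    "P_L_Na_a": "N_Na_a", "P_L_K_a": "N_K_a", "P_L_Cl_a": "N_Cl_a",
    "P_L_Ca_a": "N_Ca_a", "P_L_Glu_a": "N_Glu_a",
}


def estimate_leak_permeabilities(y0: np.ndarray, totals: ConservedTotals,
                                 geom: Geometry, consts: PhysicalConstants,
                                 tp: TransportParams,
                                 vp: VesicleParams) -> dict:
    """Leak permeabilities P_L^{X,i} that make the baseline an equilibrium.

    Each species/compartment amount equation is linear in its own leak
    permeability, so P_L = -RHS(P_L=0) / dRHS/dP_L.  A negative solution
    (a leak that would have to run against its electrochemical gradient)
    raises; a vanishing GHK factor with a non-zero residual is infeasible.
    """
    from .simulate import rhs_autonomous  # local import avoids a cycle

    zeroed = {k: 0.0 for k in _LEAK_TO_STATE}
    tp0 = tp.copy(**zeroed)
    r0 = rhs_autonomous(y0, totals, geom, consts, tp0, vp, energy=1.0)
    leaks: dict[str, float] = {}
    for leak, state_name in _LEAK_TO_STATE.items():
        idx = STATE_NAMES.index(state_name)
        tp1 = tp.copy(**{**zeroed, leak: 1.0})
        r1 = rhs_autonomous(y0, totals, geom, consts, tp1, vp, energy=1.0)
        slope = r1[idx] - r0[idx]
        if abs(slope) < 1e-30:
            if abs(r0[idx]) > 1e-18:
                raise CalibrationError(
                    f"{leak}: zero leak driving force with non-zero residual")
            leaks[leak] = 0.0
            continue
        p = -r0[idx] / slope
        if p < 0:
            raise CalibrationError(
                f"{leak} = {p:.3e} < 0: baseline infeasible under the "
                "package's transporter sign conventions")
        leaks[leak] = p
    return leaks


def recalibrate_for_pscale(model: "Model", P_scale: float) -> "Model":
    """Return a model with the pump rescaled and leaks recomputed so the
    baseline state is unchanged and remains an equilibrium."""
    if P_scale <= 0:
        raise ValueError("P_scale must be positive")
    tp = model.tp.copy(P_scale=P_scale)
    leaks = estimate_leak_permeabilities(model.y0, model.totals, model.geom,
                                         model.consts, tp, model.vp)
    tp = tp.copy(**leaks)
    report = dict(model.report)
    report["P_scale"] = P_scale
    report["leak_permeabilities"] = leaks
    m2 = Model(consts=model.consts, geom=model.geom, baseline=model.baseline,
               totals=model.totals, tp=tp, vp=model.vp, y0=model.y0.copy(),
               report=report)
    m2.report["baseline_residual_inf"] = baseline_residual(m2)
    return m2


def baseline_residual(model: "Model") -> float:
    from .simulate import rhs_autonomous

    r = rhs_autonomous(model.y0, model.totals, model.geom, model.consts,
                       model.tp, model.vp, energy=1.0)
    return float(np.max(np.abs(r)))


# ---------------------------------------------------------------------------
# top-level calibration
# ---------------------------------------------------------------------------

def calibrate(alpha_e: float = 0.2, P_scale: float = 1.0,
              consts: PhysicalConstants | None = None,
              geom: Geometry | None = None,
              baseline: BaselineSpec | None = None,
              tp: TransportParams | None = None,
              vp: VesicleParams | None = None,
              pool_mode: str = "table") -> Model:
    """Fully calibrate the model for a given extracellular volume fraction.

    Returns a :class:`Model` whose baseline state is an equilibrium of the
    complete system; the calibration report records every derived quantity
    and the final residual norm.
    """
    consts = consts or PhysicalConstants()
    geom = geom or Geometry(alpha_e=alpha_e)
    baseline = baseline or BaselineSpec()
    tp = (tp or TransportParams()).copy(P_scale=P_scale)
    vp = vp or VesicleParams()

    if math.isnan(vp.k_m2cat):
        vp = vp.copy(k_m2cat=calibrate_vesicle_backrate(baseline, vp))

    if pool_mode != "table":
        pools = init_glutamate_pools(baseline, vp, consts, mode=pool_mode)
        baseline = baseline.copy(N_D0=pools["N_D"], N_N0=pools["N_N"],
                                 N_R0=pools["N_R"], N_R10=pools["N_R1"],
                                 N_R20=pools["N_R2"], N_R30=pools["N_R3"])

    imps = estimate_impermeants(baseline, consts, geom)
    totals = conserved_totals(baseline, geom, consts, impermeants=imps)
    y0 = initial_state(baseline, geom, consts)
    leaks = estimate_leak_permeabilities(y0, totals, geom, consts, tp, vp)
    tp = tp.copy(**leaks)

    model = Model(consts=consts, geom=geom, baseline=baseline, totals=totals,
                  tp=tp, vp=vp, y0=y0)
    resid = baseline_residual(model)
    if resid > 1e-6:
        raise CalibrationError(
            f"baseline residual {resid:.3e} fmol/ms after calibration")
    model.report = {
        "alpha_e": geom.alpha_e,
        "P_scale": P_scale,
        "W_e0": geom.W_e0,
        "W_tot": geom.W_tot,
        "impermeants": {"N_A_n": imps[0], "N_A_a": imps[1], "N_A_e": imps[2],
                        "N_B_a": imps[3], "N_B_e": imps[4]},
        "conserved_totals": {k: getattr(totals, k) for k in
                             ("C_Na", "C_K", "C_Cl", "C_Ca", "C_Glu", "C_W")},
        "net_charge": totals.net_charge(),
        "leak_permeabilities": leaks,
        "k_m2cat": vp.k_m2cat,
        "baseline_residual_inf": resid,
        "pool_mode": pool_mode,
    }
    log.info("calibrated alpha_e=%.2f P_scale=%.2f residual=%.2e",
             geom.alpha_e, P_scale, resid)
    return model
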