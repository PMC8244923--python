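"""Ca2+-dependent vesicular glutamate recycling.

Free ("inactive") presynaptic glutamate N_I is recruited into a vesicle depot
N_D, matures through a non-releasable pool N_N and a readily-releasable chain
N_R -> N_R1 -> N_R2 -> N_R3 (vesicles bound by 0..3 Ca2+ ions) and fuses into
the cleft pool N_F at rate k4.  N_F is not integrated: it follows from total
glutamate conservation.  Released glutamate re-enters N_I through EAAT and the
electrodiffusive leak, closing the cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .core import (I_D, I_GLU_A, I_GLU_N, I_N, I_R, I_R1, I_R2, I_R3,
                   ConservedTotals, ModelState)

log = logging.getLogger(__name__)

__all__ = ["VesicleParams", "vesicle_rates", "fused_pool", "pool_rhs"]


@dataclass
class VesicleParams:
    """Vesicle-cycle rate constants (ms^-1 unless noted).

    ``k_m2cat`` (the Ca2+-catalysed un-priming rate) is calibrated so the
    baseline pool occupancies are a steady state of the cycle; set it
    explicitly to override.  ``tau_rec`` is the depot-recruitment factor in
    ms/fmol, ``k3`` in 1/(mM ms), ``K_M``/``K_Dv`` in mM.
    """

    k1_max: float = 1.0
    K_M: float = 2.3e-3
    K_Dv: float = 1e-4
    k20: float = 2.1e-5
    k2_cat: float = 2e-2
    k_m20: float = 1.7e-5
    k_m2cat: float = math.nan   # calibrated (see calibrate.calibrate)
    k_m1: float = 5e-5
    k3: float = 4.4
    k_m3: float = 5.6e-2
    k4: float = 1.45
    tau_rec: float = 30.0

    def __post_init__(self) -> None:
        for name in ("k1_max", "K_M", "K_Dv", "k20", "k2_cat", "k_m20",
                     "k_m1", "k3", "k_m3", "k4", "tau_rec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def copy(self, **changes) -> "VesicleParams":
        return replace(self, **changes)


def vesicle_rates(ca_n: float, params: VesicleParams) -> tuple[float, float, float]:
    """(k1, k2, k_m2) at presynaptic Ca2+ concentration ``ca_n`` (mM).

    k1 = k1_max ca/(ca + K_M); the priming/unpriming rates are catalysed by a
    Ca2+-bound catalyst with occupancy g = ca/(ca + K_Dv):
    k2 = k20 + g k2_cat, k_m2 = k_m20 + g k_m2cat.
    """
    if ca_n < 0:
        raise ValueError("ca_n must be non-negative")
    k_m2cat = 0.0 if math.isnan(params.k_m2cat) else params.k_m2cat
    g = ca_n / (ca_n + params.K_Dv) if ca_n > 0 else 0.0
    k1 = params.k1_max * ca_n / (ca_n + params.K_M) if ca_n > 0 else 0.0
    return k1, params.k20 + g * params.k2_cat, params.k_m20 + g * k_m2cat


def fused_pool(state, totals: ConservedTotals, warn_tol: float = 1e-9) -> float:
    """Cleft (fused) glutamate N_F from total-glutamate conservation, in fmol.

    N_F = C_Glu - (N_I + N_D + N_N + N_R + N_R1 + N_R2 + N_R3 + N_Glu_a),
    floored at 0; a deficit beyond ``warn_tol`` * C_Glu is logged as a
    conservation warning.
    """
    y = state.as_array() if isinstance(state, ModelState) else state
    pool_sum = (y[I_GLU_N] + y[I_D] + y[I_N] + y[I_R] + y[I_R1] + y[I_R2]
                + y[I_R3] + y[I_GLU_A])
    n_f = totals.C_Glu - pool_sum
    if n_f < -warn_tol * totals.C_Glu:
        log.warning("glutamate conservation deficit: N_F = %.3e fmol", n_f)
    return max(n_f, 0.0)


def pool_rhs(n_i: float, n_d: float, n_n: float, n_r: float, n_r1: float,
             n_r2: float, n_r3: float, ca_n: float, params: VesicleParams,
             glu_uptake: float) -> tuple[float, float, float, float, float,
                                         float, float]:
    """Time derivatives of (N_I, N_D, N_N, N_R, N_R1, N_R2, N_R3) in fmol/ms.

    ``glu_uptake`` is the molar EAAT + leak glutamate flux into the neuron
    (fmol/ms, positive inward); fusion k4 N_R3 drains into the cleft pool
    implicitly via conservation.
    """
    k1, k2, k_m2 = vesicle_rates(ca_n, params)
    k3ca = params.k3 * ca_n
    k_m1, k_m3, k4 = params.k_m1, params.k_m3, params.k4
    recruit = n_i * n_d / params.tau_rec
    d_i = -recruit + glu_uptake
    d_d = recruit - k1 * n_d + k_m1 * n_n
    d_n = k1 * n_d - (k_m1 + k2) * n_n + k_m2 * n_r
    d_r = k2 * n_n - (k_m2 + 3.0 * k3ca) * n_r + k_m3 * n_r1
    d_r1 = 3.0 * k3ca * n_r - (k_m3 + 2.0 * k3ca) * n_r1 + 2.0 * k_m3 * n_r2
    d_r2 = 2.0 * k3ca * n_r1 - (2.0 * k_m3 + k3ca) * n_r2 + 3.0 * k_m3 * n_r3
    d_r3 = k3ca * n_r2 - (3.0 * k_m3 + k4) * n_r3
    return d_i, d_d, d_n, d_r, d_r1, d_r2, d_r3
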