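"""Domain types and the algebraic layer of the tripartite-synapse model.

The model tracks molar amounts of Na+, K+, Cl-, Ca2+ and glutamate in a
neuronal and an astrocytic compartment, Hodgkin-Huxley gates, six vesicular
glutamate pools and the two somatic volumes.  The extracellular space is
closed algebraically through conservation of mass and volume, so membrane
potentials, concentrations and osmotic gradients are *derived* quantities,
computed here and consumed by every other module.

Unit system (package-wide)
--------------------------
concentration  mM
amount         fmol
volume         1e3 um^3   (so 1 fmol / (1e3 um^3) = 1 mM exactly)
time           ms
potential      mV
current        pA         (1 pA / F integrates amounts in fmol/ms)
capacitance    pF

With Faraday's constant in C/mol and the gas constant in C mV / (mol K)
no further conversion factors appear anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "PhysicalConstants",
    "Geometry",
    "ModelState",
    "ConservedTotals",
    "CompartmentView",
    "InvalidStateError",
    "GeometryCollapseError",
    "ConservationError",
    "CalibrationError",
    "STATE_NAMES",
    "membrane_potential",
    "compartment_view",
    "osmotic_gradient",
    "volume_rhs",
]


class InvalidStateError(ValueError):
    """A state vector contains non-finite or otherwise unusable entries."""


class GeometryCollapseError(ValueError):
    """The derived extracellular volume is not positive."""


class ConservationError(ValueError):
    """A derived extracellular amount violates a conservation law."""


class CalibrationError(RuntimeError):
    """Baseline calibration is infeasible (singular system, negative leak...)."""


# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "N_Na_n", "N_K_n", "N_Cl_n", "N_Ca_n", "N_Glu_n",
    "N_Na_a", "N_K_a", "N_Cl_a", "N_Ca_a", "N_Glu_a",
    "m", "h", "n_gate",
    "N_D", "N_N", "N_R", "N_R1", "N_R2", "N_R3",
    "W_n", "W_a",
)

(I_NA_N, I_K_N, I_CL_N, I_CA_N, I_GLU_N,
 I_NA_A, I_K_A, I_CL_A, I_CA_A, I_GLU_A,
 I_M, I_H, I_NGATE,
 I_D, I_N, I_R, I_R1, I_R2, I_R3,
 I_WN, I_WA) = range(21)

NSTATE = 21

#: indices of the Ca2+/glutamate sub-system (clamped in Gibbs-Donnan runs)
SYNAPTIC_INDICES = (I_CA_N, I_GLU_N, I_CA_A, I_GLU_A, I_D, I_N, I_R, I_R1, I_R2, I_R3)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and fixed synaptic geometry.

    ``F`` C/mol, ``R`` C mV/(mol K), ``T`` K, capacitances pF and the three
    fixed synaptic volumes (presynaptic terminal, cleft, perisynaptic
    astrocyte process) in 1e3 um^3.
    """

    F: float = 96485.333
    R: float = 8314.4598
    T: float = 310.0
    C_n: float = 20.0
    C_a: float = 20.0
    W_ps: float = 1e-3
    W_c: float = 1e-3
    W_pap: float = 1e-3

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")

    @property
    def rtf(self) -> float:
        """Thermal voltage RT/F in mV (26.71 mV at 310 K)."""
        return self.R * self.T / self.F


@dataclass(frozen=True)
class Geometry:
    """Baseline somatic volumes and the extracellular volume fraction.

    ``alpha_e`` is the initial extracellular volume fraction
    W_e0 / W_tot; the extracellular volume follows as
    W_e0 = alpha_e (W_n0 + W_a0) / (1 - alpha_e).
    """

    W_n0: float = 2.0
    W_a0: float = 2.0
    alpha_e: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_e < 1.0):
            raise ValueError("alpha_e must lie in (0, 1)")
        if self.W_n0 <= 0 or self.W_a0 <= 0:
            raise ValueError("baseline volumes must be positive")

    @property
    def W_e0(self) -> float:
        return self.alpha_e * (self.W_n0 + self.W_a0) / (1.0 - self.alpha_e)

    @property
    def W_tot(self) -> float:
        return self.W_n0 + self.W_a0 + self.W_e0


@dataclass
class ModelState:
    """The 21 dynamical variables, with named access.

    Amounts in fmol, gates dimensionless, volumes in 1e3 um^3.  Neuronal
    glutamate ``N_Glu_n`` is identified with the inactive pool N_I of the
    vesicle cycle; Ca2+ and glutamate amounts live in the fixed synaptic
    sub-compartments (presynaptic terminal / perisynaptic process).
    """

    N_Na_n: float
    N_K_n: float
    N_Cl_n: float
    N_Ca_n: float
    N_Glu_n: float
    N_Na_a: float
    N_K_a: float
    N_Cl_a: float
    N_Ca_a: float
    N_Glu_a: float
    m: float
    h: float
    n_gate: float
    N_D: float
    N_N: float
    N_R: float
    N_R1: float
    N_R2: float
    N_R3: float
    W_n: float
    W_a: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (NSTATE,):
            raise InvalidStateError(f"state vector must have length {NSTATE}")
        if not np.all(np.isfinite(y)):
            raise InvalidStateError("state vector contains non-finite entries")
        return cls(**dict(zip(STATE_NAMES, y.tolist())))

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise InvalidStateError("non-finite state entry")
        for q in (self.m, self.h, self.n_gate):
            if not (0.0 <= q <= 1.0):
                raise InvalidStateError("gating variables must lie in [0, 1]")


@dataclass(frozen=True)
class ConservedTotals:
    """Conserved totals and impermeant-ion amounts.

    ``C_X`` is the total amount of species X over all compartments, ``C_W``
    the total volume.  The impermeant anions A- and cations B+ have fixed
    amounts per compartment (the neuron carries only A-); they keep the
    resting potentials and the osmotic balance and close the global charge
    budget: sum_X z_X C_X - N_A_n - N_A_a - N_A_e + N_B_a + N_B_e = 0.
    """

    C_Na: float
    C_K: float
    C_Cl: float
    C_Ca: float
    C_Glu: float
    C_W: float
    N_A_n: float
    N_A_a: float
    N_A_e: float
    N_B_a: float
    N_B_e: float

    def net_charge(self) -> float:
        """Total system charge in fmol of elementary charge (should be 0)."""
        return (self.C_Na + self.C_K - self.C_Cl + 2.0 * self.C_Ca - self.C_Glu
                - self.N_A_n - self.N_A_a - self.N_A_e + self.N_B_a + self.N_B_e)


@dataclass(slots=True)
class CompartmentView:
    """Concentrations (mM), membrane potentials (mV) and volumes.

    Na/K/Cl concentrations are shared between somatic and synaptic
    compartments; Ca2+ and glutamate are confined to the synaptic
    sub-compartments (``ca_n`` is the presynaptic-terminal concentration,
    ``ca_c``/``glu_c`` the cleft concentrations).
    """

    na_n: float
    k_n: float
    cl_n: float
    ca_n: float
    glu_n: float
    na_a: float
    k_a: float
    cl_a: float
    ca_a: float
    glu_a: float
    na_e: float
    k_e: float
    cl_e: float
    ca_c: float
    glu_c: float
    V_n: float
    V_a: float
    W_n: float
    W_a: float
    W_e: float


# ---------------------------------------------------------------------------
# algebraic layer
# ---------------------------------------------------------------------------

def neuron_charge(state: ModelState | np.ndarray, totals: ConservedTotals) -> float:
    y = state.as_array() if isinstance(state, ModelState) else state
    return (y[I_NA_N] + y[I_K_N] - y[I_CL_N] + 2.0 * y[I_CA_N] - y[I_GLU_N]
            - totals.N_A_n)


def astro_charge(state: ModelState | np.ndarray, totals: ConservedTotals) -> float:
    y = state.as_array() if isinstance(state, ModelState) else state
    return (y[I_NA_A] + y[I_K_A] - y[I_CL_A] + 2.0 * y[I_CA_A] - y[I_GLU_A]
            - totals.N_A_a + totals.N_B_a)


def membrane_potential(state, totals: ConservedTotals, consts: PhysicalConstants,
                       compartment: str) -> float:
    """Membrane potential V_i = (F / C_i) sum_X z_X N_X^i in mV.

    The sum runs over the mobile species assigned to compartment ``i``
    (including the synaptic Ca2+ and glutamate amounts) plus the compartment's
    impermeant ions.
    """
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("non-finite amounts in membrane_potential")
    if compartment == "n":
        return consts.F / consts.C_n * neuron_charge(y, totals)
    if compartment == "a":
        return consts.F / consts.C_a * astro_charge(y, totals)
    raise ValueError("compartment must be 'n' or 'a'")


def compartment_view(state, totals: ConservedTotals, geom: Geometry,
                     consts: PhysicalConstants) -> CompartmentView:
    """Derive all concentrations and potentials from a state vector.

    Extracellular Na/K/Cl are obtained from mass conservation over the
    (volume-conserving) system; cleft Ca2+ and glutamate from conservation
    over the fixed synaptic volumes.  Raises on a collapsed extracellular
    space or a negative derived extracellular amount.
    """
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, float)
    W_n, W_a = y[I_WN], y[I_WA]
    if W_n <= 0.0 or W_a <= 0.0:
        raise GeometryCollapseError("somatic volume is not positive")
    W_e = totals.C_W - W_n - W_a
    if W_e <= 0.0:
        raise GeometryCollapseError("extracellular volume collapsed (W_e <= 0)")

    N_Na_e = totals.C_Na - y[I_NA_N] - y[I_NA_A]
    N_K_e = totals.C_K - y[I_K_N] - y[I_K_A]
    N_Cl_e = totals.C_Cl - y[I_CL_N] - y[I_CL_A]
    N_Ca_c = totals.C_Ca - y[I_CA_N] - y[I_CA_A]
    tol = -1e-9 * max(totals.C_Na, totals.C_K, totals.C_Cl)
    if min(N_Na_e, N_K_e, N_Cl_e, N_Ca_c) < tol:
        raise ConservationError("negative derived extracellular amount")

    # cleft glutamate: fused pool from total-glutamate closure, floored at 0
    pool_sum = (y[I_GLU_N] + y[I_D] + y[I_N] + y[I_R] + y[I_R1] + y[I_R2]
                + y[I_R3] + y[I_GLU_A])
    N_F = totals.C_Glu - pool_sum
    if N_F < 0.0:
        N_F = 0.0

    return CompartmentView(
        na_n=y[I_NA_N] / W_n, k_n=y[I_K_N] / W_n, cl_n=y[I_CL_N] / W_n,
        ca_n=y[I_CA_N] / consts.W_ps, glu_n=y[I_GLU_N] / consts.W_ps,
        na_a=y[I_NA_A] / W_a, k_a=y[I_K_A] / W_a, cl_a=y[I_CL_A] / W_a,
        ca_a=y[I_CA_A] / consts.W_pap, glu_a=y[I_GLU_A] / consts.W_pap,
        na_e=N_Na_e / W_e, k_e=N_K_e / W_e, cl_e=N_Cl_e / W_e,
        ca_c=max(N_Ca_c, 0.0) / consts.W_c, glu_c=N_F / consts.W_c,
        V_n=consts.F / consts.C_n * neuron_charge(y, totals),
        V_a=consts.F / consts.C_a * astro_charge(y, totals),
        W_n=W_n, W_a=W_a, W_e=W_e,
    )


def osmotic_gradient(view: CompartmentView, totals: ConservedTotals,
                     consts: PhysicalConstants, compartment: str) -> float:
    """Osmotic pressure gradient RT sum_X ([X]_i - [X]_e) in mPa.

    The osmolyte set is {Na, K, Cl} plus the impermeant ions (whose amounts
    are constant but whose concentrations track the changing volumes); the
    synaptic-compartment Ca2+/glutamate do not contribute to somatic osmosis.
    Including the impermeants makes the calibrated baseline a genuine volume
    equilibrium.
    """
    imp_e = (totals.N_A_e + totals.N_B_e) / view.W_e
    osm_e = view.na_e + view.k_e + view.cl_e + imp_e
    if compartment == "n":
        osm_i = view.na_n + view.k_n + view.cl_n + totals.N_A_n / view.W_n
    elif compartment == "a":
        osm_i = (view.na_a + view.k_a + view.cl_a
                 + (totals.N_A_a + totals.N_B_a) / view.W_a)
    else:
        raise ValueError("compartment must be 'n' or 'a'")
    return consts.R * consts.T * (osm_i - osm_e)


def volume_rhs(view: CompartmentView, totals: ConservedTotals,
               consts: PhysicalConstants, L_H2O: float, compartment: str) -> float:
    """dW_i/dt = L_H2O * Delta-pi, in 1e3 um^3 / ms.

    ``L_H2O`` is the membrane water permeability in 1e3 um^3/(mPa ms); the
    osmotic flux rate of the model equations is lambda_i = L_H2O R T.
    """
    if L_H2O < 0:
        raise ValueError("water permeability must be non-negative")
    return L_H2O * osmotic_gradient(view, totals, consts, compartment)
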