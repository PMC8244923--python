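"""Transmembrane currents and fluxes.

All electrodiffusive pathways (voltage-gated channels and leaks) use the
Goldman-Hodgkin-Katz current equation; cotransporters (KCC, NKCC1, EAAT) are
log-ratio (Nernst-potential-difference) fluxes; the Na+/K+-ATPase follows the
Luo-Rudy voltage/[Na]e dependence; NCX is the standard 3:1 exchanger with an
Eyring energy-barrier voltage dependence.

Sign conventions
----------------
Currents (pA) are positive for *cation efflux* from the compartment; molar
cotransporter fluxes J (fmol/ms) are positive *into* the compartment for the
carried substrate (glutamate for EAAT, K+ and Cl- for KCC, Na+/K+/2Cl- for
NKCC1).  Amount equations then read dN/dt = -I/(z F) plus the molar fluxes
with their stoichiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum

from .core import CompartmentView, PhysicalConstants

__all__ = [
    "TransportParams",
    "Pathway",
    "Blockade",
    "ghk",
    "nernst",
    "gate_rates",
    "gate_rhs",
    "gated_ca_activation",
    "gated_currents",
    "nka_current",
    "kcc_flux",
    "kir_current",
    "nkcc1_flux",
    "ncx_current",
    "eaat_flux",
    "leak_current",
]

# removable-singularity switch width (dimensionless GHK exponent / mV in rates)
_SING = 1e-7
# floor used inside cotransporter logs so a transiently empty cleft cannot
# produce -inf; the deficit is physically meaningless at this scale
GLU_FLOOR = 1e-12


class Pathway(str, Enum):
    """Public, stable names of the blockable transport pathways."""

    GATED_NA_N = "gated_na_n"
    GATED_K_N = "gated_k_n"
    GATED_CL_N = "gated_cl_n"
    GATED_CA_N = "gated_ca_n"
    NKA_N = "nka_n"
    KCC_N = "kcc_n"
    NCX_N = "ncx_n"
    EAAT_N = "eaat_n"
    LEAK_N = "leak_n"
    NKA_A = "nka_a"
    KIR_A = "kir_a"
    NKCC1_A = "nkcc1_a"
    NCX_A = "ncx_a"
    EAAT_A = "eaat_a"
    LEAK_A = "leak_a"


_ASTRO_PATHWAYS = (Pathway.NKA_A, Pathway.KIR_A, Pathway.NKCC1_A,
                   Pathway.NCX_A, Pathway.EAAT_A, Pathway.LEAK_A)


@dataclass
class Blockade:
    """Multiplicative factor in [0, 1] per pathway (0 = fully blocked)."""

    factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for k, v in self.factors.items():
            p = Pathway(k)
            if not (0.0 <= float(v) <= 1.0):
                raise ValueError(f"blockade factor for {p.value} outside [0,1]")
            clean[p] = float(v)
        self.factors = clean

    def factor(self, pathway: Pathway) -> float:
        return self.factors.get(pathway, 1.0)

    @classmethod
    def astrocyte_off(cls) -> "Blockade":
        """Block all ion transport across the astrocytic membrane."""
        return cls({p: 0.0 for p in _ASTRO_PATHWAYS})


@dataclass
class TransportParams:
    """Channel/transporter strengths and half-saturations.

    Gated and leak permeabilities are in 1e3 um^3/ms, pump strengths in pA,
    cotransporter strengths in fmol/(ms mV), Kir conductance in nS, water
    permeabilities in 1e3 um^3/(mPa ms).  Leak permeabilities default to NaN
    and are filled in by calibration so the configured baseline is an exact
    equilibrium.
    """

    # neuronal voltage-gated channels
    P_G_Na_n: float = 8e-4
    P_G_K_n: float = 4e-4
    P_G_Cl_n: float = 1.95e-5
    P_G_Ca_n: float = 1.5e-5
    # gated Ca2+ steady-state activation a(V) = sigmoid((V - vhalf)/slope)^power
    # (high-threshold: closed at rest, opens near the action-potential peak;
    # the defaults are pinned by the stimulated-burst benchmark)
    ca_act_vhalf: float = 12.0
    ca_act_slope: float = 5.0
    ca_act_power: int = 2
    # Na/K-ATPase (both cells)
    P_NKA_n: float = 86.4
    P_NKA_a: float = 86.4
    alpha_NKA_Na: float = 13.0
    alpha_NKA_K: float = 0.2
    P_scale: float = 1.0
    # voltage-factor variant: "saturating" is the reciprocal Luo-Rudy form
    # (pump weakens with depolarization); "driven" is its inverse (pump
    # strengthens with depolarization)
    nka_g_form: str = "saturating"
    # KCC (neuron)
    P_KCl_n: float = 1.3e-6
    # Kir4.1 and NKCC1 (astrocyte)
    P_Kir_a: float = 0.286102
    P_NKCC1_a: float = 7.3215e-7
    # NCX (both cells)
    P_NCX_n: float = 10.8
    P_NCX_a: float = 5.7
    alpha_NCX_Na: float = 87.5
    alpha_NCX_Ca: float = 1.38
    eta_NCX: float = 0.35
    k_NCX: float = 0.1
    # EAAT (both cells); alpha_H is the fixed cleft/cytosol proton ratio
    P_EAAT_n: float = 1e-6
    P_EAAT_a: float = 2e-5
    alpha_H_n: float = 0.66
    alpha_H_a: float = 0.66
    # water permeabilities
    L_H2O_n: float = 2e-14
    L_H2O_a: float = 2e-14
    # leak permeabilities (calibrated)
    P_L_Na_n: float = math.nan
    P_L_K_n: float = math.nan
    P_L_Cl_n: float = math.nan
    P_L_Ca_n: float = math.nan
    P_L_Glu_n: float = math.nan
    P_L_Na_a: float = math.nan
    P_L_K_a: float = math.nan
    P_L_Cl_a: float = math.nan
    P_L_Ca_a: float = math.nan
    P_L_Glu_a: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 < self.eta_NCX < 1.0):
            raise ValueError("eta_NCX must lie in (0, 1)")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("P_", "L_", "alpha_", "k_NCX")):
                if isinstance(v, float) and not math.isnan(v) and v < 0:
                    raise ValueError(f"{f.name} must be non-negative")

    def leaks_calibrated(self) -> bool:
        return not any(math.isnan(getattr(self, f"P_L_{x}_{i}"))
                       for x in ("Na", "K", "Cl", "Ca", "Glu") for i in ("n", "a"))

    def copy(self, **changes) -> "TransportParams":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# elementary electro-diffusion
# ---------------------------------------------------------------------------

def _safe_exp(x: float) -> float:
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return math.exp(x)


def ghk(v: float, c_in: float, c_out: float, z: int,
        consts: PhysicalConstants) -> float:
    """Goldman-Hodgkin-Katz flux density (current per unit permeability).

    F^2 V z^2/(RT) (c_in - c_out e^{-FVz/RT}) / (1 - e^{-FVz/RT}); the
    removable singularity at V = 0 is evaluated by its series expansion
    F z [(c_in - c_out) + x (c_in + c_out)/2] with x = FVz/RT.
    """
    x = v * z / consts.rtf
    Fz = consts.F * z
    if abs(x) < _SING:
        return Fz * ((c_in - c_out) + 0.5 * x * (c_in + c_out))
    e = _safe_exp(-x)
    return Fz * x * (c_in - c_out * e) / (1.0 - e)


def nernst(c_out: float, c_in: float, z: int, consts: PhysicalConstants) -> float:
    """Nernst reversal potential (RT / zF) ln(c_out / c_in) in mV."""
    if c_out <= 0.0 or c_in <= 0.0:
        raise ValueError("Nernst potential requires positive concentrations")
    return consts.rtf / z * math.log(c_out / c_in)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gating
# ---------------------------------------------------------------------------

def _vtrap(x: float, s: float) -> float:
    """x / (1 - exp(-x/s)) with its limit s at x -> 0."""
    if abs(x) < _SING:
        return s + 0.5 * x
    return x / (1.0 - _safe_exp(-x / s))


def _vtrap2(x: float, s: float) -> float:
    """x / (exp(x/s) - 1) with its limit s at x -> 0."""
    if abs(x) < _SING:
        return s - 0.5 * x
    return x / (_safe_exp(x / s) - 1.0)


def gate_rates(v: float) -> tuple[float, float, float, float, float, float]:
    """(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n) in 1/ms.

    Standard cortical-neuron rate functions; the removable singularities at
    V = -52 (alpha_m), -25 (beta_m) and -35 (alpha_n) are evaluated by their
    limits.
    """
    a_m = 0.32 * _vtrap(v + 52.0, 4.0)
    b_m = 0.28 * _vtrap2(v + 25.0, 5.0)
    a_h = 0.128 * _safe_exp(-(v + 53.0) / 18.0)
    b_h = 4.0 / (1.0 + _safe_exp(-(v + 30.0) / 5.0))
    a_n = 0.016 * _vtrap(v + 35.0, 5.0)
    b_n = 0.25 * _safe_exp(-(v + 50.0) / 40.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def gate_rhs(q: float, alpha: float, beta: float) -> float:
    """dq/dt = alpha (1 - q) - beta q."""
    return alpha * (1.0 - q) - beta * q


def gate_steady_state(v: float) -> tuple[float, float, float]:
    """(m_inf, h_inf, n_inf) at potential v."""
    a_m, b_m, a_h, b_h, a_n, b_n = gate_rates(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


def gated_ca_activation(v: float, params: TransportParams) -> float:
    """Instantaneous activation of the voltage-gated Ca2+ channel.

    A high-threshold Boltzmann raised to an integer power,
    a(V) = [1 + exp(-(V - vhalf)/slope)]^(-power).  The channel is
    effectively closed at rest and opens only during action potentials.
    """
    s = 1.0 / (1.0 + _safe_exp(-(v - params.ca_act_vhalf) / params.ca_act_slope))
    return s ** params.ca_act_power


def gated_currents(view: CompartmentView, m: float, h: float, n_gate: float,
                   params: TransportParams, consts: PhysicalConstants,
                   blockade: Blockade | None = None,
                   ) -> tuple[float, float, float, float]:
    """Neuronal voltage-gated (Na, K, Cl, Ca) currents in pA.

    Transient Na+ gates as m^3 h; the delayed-rectifier K+ current gates as
    n^2 (the exponent of the source model for these rate functions — with a
    steeper exponent the GHK Na+ window current overwhelms the rectifier and
    the neuron cannot fire repetitively); the Cl- channel carries a sigmoidal
    voltage dependence and the Ca2+ channel an instantaneous high-threshold
    activation.
    """
    bl = blockade or _NO_BLOCK
    v = view.V_n
    i_na = (bl.factor(Pathway.GATED_NA_N) * params.P_G_Na_n * m ** 3 * h
            * ghk(v, view.na_n, view.na_e, 1, consts))
    i_k = (bl.factor(Pathway.GATED_K_N) * params.P_G_K_n * n_gate ** 2
           * ghk(v, view.k_n, view.k_e, 1, consts))
    i_cl = (bl.factor(Pathway.GATED_CL_N) * params.P_G_Cl_n
            / (1.0 + _safe_exp(-(v + 10.0) / 10.0))
            * ghk(v, view.cl_n, view.cl_e, -1, consts))
    i_ca = (bl.factor(Pathway.GATED_CA_N) * params.P_G_Ca_n
            * gated_ca_activation(v, params)
            * ghk(v, view.ca_n, view.ca_c, 2, consts))
    return i_na, i_k, i_cl, i_ca


# ---------------------------------------------------------------------------
# pumps and exchangers
# ---------------------------------------------------------------------------

def nka_current(view: CompartmentView, params: TransportParams,
                consts: PhysicalConstants, energy_fraction: float,
                compartment: str, blockade: Blockade | None = None) -> float:
    """Na+/K+-ATPase cycle current I_NKA in pA (3 Na+ out, 2 K+ in per I).

    I = energy * P_scale * P_NKA * g(V, [Na]e) * Hill_1.5([Na]i) * Hill([K]e)
    with the Luo-Rudy voltage factor
    g = 1 / (1 + 0.1245 e^{-0.1 FV/RT} + 0.0365 sigma e^{-FV/RT}),
    sigma = (e^{[Na]e/67.3} - 1)/7.
    """
    bl = blockade or _NO_BLOCK
    if not (0.0 <= energy_fraction <= 1.5 + 1e-9):
        # continuation explores pump strengths above 100%; guard nonsense only
        if not math.isfinite(energy_fraction) or energy_fraction < 0:
            raise ValueError("energy_fraction must be finite and >= 0")
    if compartment == "n":
        v, na_i, p, f = view.V_n, view.na_n, params.P_NKA_n, bl.factor(Pathway.NKA_N)
    else:
        v, na_i, p, f = view.V_a, view.na_a, params.P_NKA_a, bl.factor(Pathway.NKA_A)
    x = v / consts.rtf
    sigma = (_safe_exp(view.na_e / 67.3) - 1.0) / 7.0
    g = 1.0 + 0.1245 * _safe_exp(-0.1 * x) + 0.0365 * sigma * _safe_exp(-x)
    if params.nka_g_form == "saturating":
        g = 1.0 / g
    na15 = na_i ** 1.5 if na_i > 0 else 0.0
    hill_na = na15 / (na15 + params.alpha_NKA_Na ** 1.5)
    hill_k = view.k_e / (view.k_e + params.alpha_NKA_K) if view.k_e > 0 else 0.0
    return f * energy_fraction * params.P_scale * p * g * hill_na * hill_k


def kcc_flux(view: CompartmentView, params: TransportParams,
             consts: PhysicalConstants, blockade: Blockade | None = None) -> float:
    """K-Cl cotransporter molar flux J (fmol/ms), positive into the neuron.

    J = P_KCl (RT/F) ln([K]e [Cl]e / ([K]n [Cl]n)); K+ and Cl- both move
    with J (electroneutral symport), so the baseline gradient drives efflux.
    """
    bl = blockade or _NO_BLOCK
    num = view.k_e * view.cl_e
    den = view.k_n * view.cl_n
    if num <= 0.0 or den <= 0.0:
        raise ValueError("KCC requires positive K+/Cl- concentrations")
    return (bl.factor(Pathway.KCC_N) * params.P_KCl_n * consts.rtf
            * math.log(num / den))


def kir_current(view: CompartmentView, params: TransportParams,
                consts: PhysicalConstants, blockade: Blockade | None = None) -> float:
    """Astrocytic Kir4.1 K+ current in pA (vanishes at V_a = E_K).

    I = P_Kir m_inf [K]e/([K]e + 13) (V_a - E_K),
    m_inf = (2 + exp(1.62 (F/RT)(V_a - E_K)))^-1.
    """
    bl = blockade or _NO_BLOCK
    e_k = nernst(view.k_e, view.k_a, 1, consts)
    dv = view.V_a - e_k
    m_inf = 1.0 / (2.0 + _safe_exp(1.62 * dv / consts.rtf))
    sat = view.k_e / (view.k_e + 13.0)
    return bl.factor(Pathway.KIR_A) * params.P_Kir_a * m_inf * sat * dv


def nkcc1_flux(view: CompartmentView, params: TransportParams,
               consts: PhysicalConstants, blockade: Blockade | None = None) -> float:
    """NKCC1 molar flux J (fmol/ms), positive into the astrocyte.

    J = P_NKCC1 (RT/F) ln( ([Na]e/[Na]a)([K]e/[K]a)([Cl]e/[Cl]a)^2 );
    carries 1 Na+, 1 K+ and 2 Cl- per J.
    """
    bl = blockade or _NO_BLOCK
    args = (view.na_e / view.na_a, view.k_e / view.k_a, view.cl_e / view.cl_a)
    if min(view.na_e, view.na_a, view.k_e, view.k_a, view.cl_e, view.cl_a) <= 0.0:
        raise ValueError("NKCC1 requires positive concentrations")
    return (bl.factor(Pathway.NKCC1_A) * params.P_NKCC1_a * consts.rtf
            * math.log(args[0] * args[1] * args[2] ** 2))


def ncx_current(view: CompartmentView, params: TransportParams,
                consts: PhysicalConstants, compartment: str,
                blockade: Blockade | None = None) -> float:
    """Na+/Ca2+ exchanger current in pA (3 Na+ per Ca2+).

    Forward mode (Ca2+ extrusion) gives I < 0; the current reverses when the
    Na+ term outgrows the Ca2+ term, as happens under Na+ loading.
    """
    bl = blockade or _NO_BLOCK
    if compartment == "n":
        v, na_i, ca_i, p, f = (view.V_n, view.na_n, view.ca_n, params.P_NCX_n,
                               bl.factor(Pathway.NCX_N))
    else:
        v, na_i, ca_i, p, f = (view.V_a, view.na_a, view.ca_a, params.P_NCX_a,
                               bl.factor(Pathway.NCX_A))
    if view.ca_c <= 0.0:
        raise ValueError("NCX requires positive cleft Ca2+")
    x = v / consts.rtf
    na_e3 = view.na_e ** 3
    hill_na = na_e3 / (params.alpha_NCX_Na ** 3 + na_e3)
    hill_ca = view.ca_c / (params.alpha_NCX_Ca + view.ca_c)
    fwd = (na_i / view.na_e) ** 3 * _safe_exp(params.eta_NCX * x)
    rev = (ca_i / view.ca_c) * _safe_exp((params.eta_NCX - 1.0) * x)
    den = 1.0 + params.k_NCX * _safe_exp((params.eta_NCX - 1.0) * x)
    return f * p * hill_na * hill_ca * (fwd - rev) / den


def eaat_flux(view: CompartmentView, params: TransportParams,
              consts: PhysicalConstants, compartment: str,
              blockade: Blockade | None = None) -> float:
    """EAAT molar glutamate flux J (fmol/ms), positive into the cell.

    J = P_EAAT (RT/F) ln( ([Na]e/[Na]i)^3 ([K]i/[K]e) alpha_H [Glu]c/[Glu]i );
    carries 1 Glu- and 3 Na+ in, 1 K+ out (net +2 charge influx per J).
    alpha_H is the fixed extracellular-to-intracellular proton ratio.
    """
    bl = blockade or _NO_BLOCK
    if compartment == "n":
        na_i, k_i, glu_i, p, a_h, f = (view.na_n, view.k_n, view.glu_n,
                                       params.P_EAAT_n, params.alpha_H_n,
                                       bl.factor(Pathway.EAAT_N))
    else:
        na_i, k_i, glu_i, p, a_h, f = (view.na_a, view.k_a, view.glu_a,
                                       params.P_EAAT_a, params.alpha_H_a,
                                       bl.factor(Pathway.EAAT_A))
    glu_c = max(view.glu_c, GLU_FLOOR)
    if min(view.na_e, na_i, k_i, view.k_e, glu_i) <= 0.0:
        raise ValueError("EAAT requires positive concentrations")
    arg = (view.na_e / na_i) ** 3 * (k_i / view.k_e) * a_h * (glu_c / glu_i)
    return f * p * consts.rtf * math.log(arg)


def leak_current(view: CompartmentView, params: TransportParams,
                 consts: PhysicalConstants, species: str, compartment: str,
                 blockade: Blockade | None = None) -> float:
    """GHK leak current P_L^{X,i} GHK(V_i, [X]_i, [X]_e) in pA."""
    bl = blockade or _NO_BLOCK
    z = {"Na": 1, "K": 1, "Cl": -1, "Ca": 2, "Glu": -1}[species]
    p = getattr(params, f"P_L_{species}_{compartment}")
    if compartment == "n":
        v, f = view.V_n, bl.factor(Pathway.LEAK_N)
        c_in = {"Na": view.na_n, "K": view.k_n, "Cl": view.cl_n,
                "Ca": view.ca_n, "Glu": view.glu_n}[species]
    else:
        v, f = view.V_a, bl.factor(Pathway.LEAK_A)
        c_in = {"Na": view.na_a, "K": view.k_a, "Cl": view.cl_a,
                "Ca": view.ca_a, "Glu": view.glu_a}[species]
    c_out = {"Na": view.na_e, "K": view.k_e, "Cl": view.cl_e,
             "Ca": view.ca_c, "Glu": view.glu_c}[species]
    return f * p * ghk(v, c_in, c_out, z, consts)


_NO_BLOCK = Blockade()
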