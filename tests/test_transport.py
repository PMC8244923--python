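"""Transport pathways: reversal conditions, limits, and a high-precision
independent oracle for the full current evaluation."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trisyn as ts
from trisyn.transport import (Blockade, Pathway, eaat_flux, gate_rates,
                              gate_rhs, gate_steady_state, gated_ca_activation,
                              gated_currents, ghk, kcc_flux, kir_current,
                              leak_current, nernst, ncx_current, nka_current,
                              nkcc1_flux)

C = ts.PhysicalConstants()
RTF = C.rtf


# ---------------------------------------------------------------------------
# GHK electrodiffusion
# ---------------------------------------------------------------------------

def ghk_mp(v, c_in, c_out, z):
    """Arbitrary-precision evaluation of the GHK current density."""
    with mpmath.workdps(50):
        v, c_in, c_out, z = map(mpmath.mpf, (v, c_in, c_out, z))
        F, R, T = mpmath.mpf("96485.333"), mpmath.mpf("8314.4598"), mpmath.mpf(310)
        x = F * v * z / (R * T)
        if x == 0:
            return float(F * z * (c_in - c_out))
        return float(F * z * x * (c_in - c_out * mpmath.e**-x) / (1 - mpmath.e**-x))


def test_ghk_zero_at_equilibrium():
    assert ghk(0.0, 5.0, 5.0, 1, C) == pytest.approx(0.0, abs=1e-12)


def test_ghk_ohmic_identity():
    # equal concentrations: GHK reduces to z^2 F^2 V c / (RT) exactly
    for v in (-80.0, -1e-3, 26.7, 120.0):
        for z in (1, -1, 2):
            got = ghk(v, 10.0, 10.0, z, C)
            assert got == pytest.approx(z * z * C.F * C.F * v * 10.0 / (C.R * C.T),
                                        rel=1e-7)


def test_ghk_matches_arbitrary_precision_oracle():
    # thermal voltage, 2:1 gradient — and a grid of other states
    assert ghk(26.7137, 10.0, 5.0, 1, C) == pytest.approx(
        ghk_mp(26.7137, 10.0, 5.0, 1), rel=1e-12)
    rng = np.random.default_rng(42)
    for _ in range(100):
        v = rng.uniform(-120, 60)
        c_in, c_out = rng.uniform(1e-4, 160, size=2)
        z = rng.choice([-1, 1, 2])
        assert ghk(v, c_in, c_out, int(z), C) == pytest.approx(
            ghk_mp(v, c_in, c_out, int(z)), rel=1e-10)


def test_ghk_continuous_at_singularity():
    eps = 1e-8 * RTF
    below = ghk(-eps, 12.0, 5.0, 1, C)
    above = ghk(eps, 12.0, 5.0, 1, C)
    at = ghk(0.0, 12.0, 5.0, 1, C)
    assert math.isfinite(at)
    assert below == pytest.approx(at, rel=1e-6)
    assert above == pytest.approx(at, rel=1e-6)
    assert at == pytest.approx(C.F * (12.0 - 5.0), rel=1e-7)


def test_ghk_vanishes_at_nernst_potential():
    for z in (1, -1, 2):
        e_rev = nernst(5.0, 50.0, z, C)
        assert ghk(e_rev, 50.0, 5.0, z, C) == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Nernst potentials
# ---------------------------------------------------------------------------

def test_nernst_values():
    assert nernst(10.0, 10.0, 1, C) == 0.0
    assert nernst(10.0 * math.e, 10.0, 1, C) == pytest.approx(26.7137, abs=1e-3)
    assert nernst(100.0, 10.0, 1, C) == pytest.approx(61.51, abs=0.01)
    assert nernst(100.0, 10.0, -1, C) == pytest.approx(-61.51, abs=0.01)


def test_nernst_domain_error():
    with pytest.raises(ValueError):
        nernst(0.0, 1.0, 1, C)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def test_gate_rate_limits_at_singularities():
    a_m, *_ = gate_rates(-52.0)
    assert a_m == pytest.approx(0.32 * 4.0, rel=1e-7)
    *_, a_n, _bn = gate_rates(-35.0)
    assert a_n == pytest.approx(0.016 * 5.0, rel=1e-7)
    _, b_m, *_ = gate_rates(-25.0)
    assert b_m == pytest.approx(0.28 * 5.0, rel=1e-7)


def test_gate_rate_direct_value():
    _, _, _, b_h, _, _ = gate_rates(-30.0)
    assert b_h == pytest.approx(2.0, rel=1e-12)  # 4 / (1 + e^0)


@given(st.floats(min_value=-150, max_value=80))
@settings(max_examples=200, deadline=None)
def test_gate_rates_finite_everywhere(v):
    assert all(math.isfinite(r) and r >= 0 for r in gate_rates(v))


def test_gate_rhs_steady_state():
    a, b = 0.3, 0.7
    q = a / (a + b)
    assert gate_rhs(q, a, b) == pytest.approx(0.0, abs=1e-15)
    assert gate_rhs(0.0, a, b) == a
    assert gate_rhs(1.0, a, b) == -b


def test_gate_steady_state_matches_baseline():
    m0, h0, n0 = gate_steady_state(-65.5)
    assert m0 == pytest.approx(1.33135e-2, rel=2e-3)
    assert h0 == pytest.approx(0.987298, rel=1e-5)
    assert n0 == pytest.approx(2.96946e-3, rel=2e-3)


# ---------------------------------------------------------------------------
# pathway reversal conditions (thermodynamic consistency)
# ---------------------------------------------------------------------------

def test_gated_na_zero_when_closed(baseline_view, model_small_ecs):
    m = model_small_ecs
    i_na, *_ = gated_currents(baseline_view, 0.0, 0.5, 0.1, m.tp, m.consts)
    assert i_na == 0.0


def test_nka_zero_without_substrate(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    v = dataclasses.replace(baseline_view, k_e=0.0)
    assert nka_current(v, m.tp, m.consts, 1.0, "n") == 0.0
    v = dataclasses.replace(baseline_view, na_n=0.0)
    assert nka_current(v, m.tp, m.consts, 1.0, "n") == 0.0


def test_nka_sigma_luo_rudy_value(baseline_view, model_small_ecs):
    # sigma([Na]e = 67.3) = (e - 1)/7
    import dataclasses
    m = model_small_ecs
    v = dataclasses.replace(baseline_view, na_e=67.3)
    i1 = nka_current(v, m.tp, m.consts, 1.0, "n")
    # replicate with explicit sigma
    x = v.V_n / RTF
    sigma = (math.e - 1.0) / 7.0
    g = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * x) + 0.0365 * sigma * math.exp(-x))
    hill_na = 13.0 ** 1.5 / (13.0 ** 1.5 + 13.0 ** 1.5)
    hill_k = 3.0 / 3.2
    assert i1 == pytest.approx(86.4 * g * hill_na * hill_k, rel=1e-12)
    assert sigma == pytest.approx(0.245469, abs=1e-6)


def test_nka_monotone_in_substrates(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    vals = [nka_current(dataclasses.replace(baseline_view, na_n=na),
                        m.tp, m.consts, 1.0, "n") for na in (5, 13, 30, 60)]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    vals = [nka_current(dataclasses.replace(baseline_view, k_e=k),
                        m.tp, m.consts, 1.0, "n") for k in (0.5, 3, 10)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_kcc_reversal_and_antisymmetry(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    v = dataclasses.replace(baseline_view, k_e=10.0, cl_e=10.0, k_n=10.0, cl_n=10.0)
    assert kcc_flux(v, m.tp, m.consts) == pytest.approx(0.0, abs=1e-15)
    # product ratio e gives P RT/F; 1/e gives the negative
    v1 = dataclasses.replace(baseline_view, k_e=math.e, cl_e=1.0, k_n=1.0, cl_n=1.0)
    v2 = dataclasses.replace(baseline_view, k_e=1.0, cl_e=1.0, k_n=math.e, cl_n=1.0)
    assert kcc_flux(v1, m.tp, m.consts) == pytest.approx(m.tp.P_KCl_n * RTF, rel=1e-10)
    assert kcc_flux(v2, m.tp, m.consts) == pytest.approx(-m.tp.P_KCl_n * RTF, rel=1e-10)


def test_kir_zero_at_donnan(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    # V_a equal to E_K: current vanishes and m_inf = 1/3
    e_k = nernst(baseline_view.k_e, baseline_view.k_a, 1, m.consts)
    v = dataclasses.replace(baseline_view, V_a=e_k)
    assert kir_current(v, m.tp, m.consts) == pytest.approx(0.0, abs=1e-12)
    v0 = dataclasses.replace(baseline_view, k_e=1e-12)
    assert kir_current(v0, m.tp, m.consts) == pytest.approx(0.0, abs=1e-9)


def test_kir_oracle_value(model_small_ecs):
    import dataclasses
    m = model_small_ecs
    v = dataclasses.replace(
        ts.compartment_view(m.y0, m.totals, m.geom, m.consts),
        V_a=-80.0, k_a=80.0, k_e=3.0)
    with mpmath.workdps(40):
        e_k = mpmath.mpf("26.71366") * 0  # computed below in full precision
        F, R, T = map(mpmath.mpf, ("96485.333", "8314.4598", "310"))
        rtf = R * T / F
        e_k = rtf * mpmath.log(mpmath.mpf(3) / 80)
        dv = mpmath.mpf(-80) - e_k
        m_inf = 1 / (2 + mpmath.e ** (mpmath.mpf("1.62") * dv / rtf))
        expected = float(mpmath.mpf("0.286102") * m_inf * (mpmath.mpf(3) / 16) * dv)
    assert kir_current(v, m.tp, m.consts) == pytest.approx(expected, rel=1e-10)


def test_nkcc1_reversal_and_log_identities(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    v = dataclasses.replace(baseline_view, na_e=10, na_a=10, k_e=4, k_a=4,
                            cl_e=30, cl_a=30)
    assert nkcc1_flux(v, m.tp, m.consts) == pytest.approx(0.0, abs=1e-15)
    # opposing Na and K gradients with balanced Cl cancel exactly
    r = 3.7
    v = dataclasses.replace(baseline_view, na_e=10 * r, na_a=10, k_e=4 / r,
                            k_a=4, cl_e=30, cl_a=30)
    assert nkcc1_flux(v, m.tp, m.consts) == pytest.approx(0.0, abs=1e-12)
    # Na+K gradient of r with a Cl gradient of 1/sqrt(r) also cancels
    sr = math.sqrt(r)
    v = dataclasses.replace(baseline_view, na_e=10 * sr, na_a=10, k_e=4 * sr,
                            k_a=4, cl_e=30 / sr, cl_a=30)
    assert nkcc1_flux(v, m.tp, m.consts) == pytest.approx(0.0, abs=1e-12)
    # log argument e
    v = dataclasses.replace(baseline_view, na_e=math.e, na_a=1.0, k_e=1.0,
                            k_a=1.0, cl_e=1.0, cl_a=1.0)
    assert nkcc1_flux(v, m.tp, m.consts) == pytest.approx(
        m.tp.P_NKCC1_a * RTF, rel=1e-10)


def test_ncx_reversal_conditions(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    # V = 0 and equal ratios
    v = dataclasses.replace(baseline_view, V_n=0.0, na_n=baseline_view.na_e,
                            ca_n=baseline_view.ca_c)
    assert ncx_current(v, m.tp, m.consts, "n") == pytest.approx(0.0, abs=1e-12)
    # general reversal: Na term equals Ca term
    v = baseline_view
    x = v.V_n / RTF
    ca_i = (v.na_n / v.na_e) ** 3 * math.exp(0.35 * x) / math.exp(-0.65 * x) * v.ca_c
    v2 = dataclasses.replace(v, ca_n=ca_i)
    assert ncx_current(v2, m.tp, m.consts, "n") == pytest.approx(0.0, abs=1e-12)


def test_ncx_oracle_value(baseline_view, model_small_ecs):
    m, v = model_small_ecs, baseline_view
    with mpmath.workdps(40):
        F, R, T = map(mpmath.mpf, ("96485.333", "8314.4598", "310"))
        x = mpmath.mpf("-65.5") * F / (R * T)
        na_e, na_i = mpmath.mpf(152), mpmath.mpf(13)
        ca_c, ca_i = mpmath.mpf("1.8"), mpmath.mpf("1e-4")
        eta, k = mpmath.mpf("0.35"), mpmath.mpf("0.1")
        hill_na = na_e ** 3 / (mpmath.mpf("87.5") ** 3 + na_e ** 3)
        hill_ca = ca_c / (mpmath.mpf("1.38") + ca_c)
        num = (na_i / na_e) ** 3 * mpmath.e ** (eta * x) \
            - (ca_i / ca_c) * mpmath.e ** ((eta - 1) * x)
        den = 1 + k * mpmath.e ** ((eta - 1) * x)
        expected = float(mpmath.mpf("10.8") * hill_na * hill_ca * num / den)
    assert ncx_current(v, m.tp, m.consts, "n") == pytest.approx(expected, rel=1e-10)


def test_eaat_log_additivity(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    j1 = eaat_flux(baseline_view, m.tp, m.consts, "n")
    v2 = dataclasses.replace(baseline_view, glu_c=2 * baseline_view.glu_c)
    j2 = eaat_flux(v2, m.tp, m.consts, "n")
    assert j2 - j1 == pytest.approx(m.tp.P_EAAT_n * RTF * math.log(2), rel=1e-9)
    # log argument 1 -> zero flux
    v3 = dataclasses.replace(baseline_view, na_e=10, na_n=10, k_n=5, k_e=5,
                             glu_c=1.0, glu_n=0.66)
    assert eaat_flux(v3, m.tp, m.consts, "n") == pytest.approx(0.0, abs=1e-12)


def test_leak_zero_at_reversal(baseline_view, model_small_ecs):
    import dataclasses
    m = model_small_ecs
    v = dataclasses.replace(baseline_view, V_n=0.0, na_n=baseline_view.na_e)
    assert leak_current(v, m.tp, m.consts, "Na", "n") == pytest.approx(0.0, abs=1e-9)
    e_na = nernst(baseline_view.na_e, baseline_view.na_n, 1, m.consts)
    v = dataclasses.replace(baseline_view, V_n=e_na)
    assert leak_current(v, m.tp, m.consts, "Na", "n") == pytest.approx(0.0, abs=1e-6)


def test_blockade_factors():
    b = Blockade({"nka_n": 0.0, Pathway.KIR_A: 0.5})
    assert b.factor(Pathway.NKA_N) == 0.0
    assert b.factor(Pathway.KIR_A) == 0.5
    assert b.factor(Pathway.EAAT_A) == 1.0
    with pytest.raises(ValueError):
        Blockade({"nka_n": 1.5})
    astro = Blockade.astrocyte_off()
    assert astro.factor(Pathway.NKA_A) == 0.0
    assert astro.factor(Pathway.NKA_N) == 1.0


def test_gated_ca_activation_negligible_at_rest(model_small_ecs):
    # the high-threshold Ca2+ channel is closed at the resting potential
    a_rest = gated_ca_activation(-65.5, model_small_ecs.tp)
    assert a_rest < 1e-6
    a_peak = gated_ca_activation(30.0, model_small_ecs.tp)
    assert a_peak > 0.5
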