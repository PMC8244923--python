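"""Calibration: impermeants, conserved totals, leak estimation, idempotence."""

import math

import numpy as np
import pytest

import trisyn as ts
from trisyn.calibrate import (BaselineSpec, baseline_residual,
                              calibrate_vesicle_backrate, conserved_totals,
                              estimate_impermeants, initial_state)
from trisyn.core import CalibrationError
from trisyn.simulate import rhs_autonomous


def test_impermeant_anion_amount_neuron(model_small_ecs):
    """The neuronal impermeant-anion amount from the capacitor rest condition:
    ~302.01 fmol for the configured baseline composition."""
    n_a_n = model_small_ecs.totals.N_A_n
    assert n_a_n == pytest.approx(302.0105, abs=0.01)


def test_impermeants_linear_sensitivity(consts):
    """Perturbing the resting potential by +1 mV changes the anion amount by
    exactly -C_n/F (linearity of the capacitor relation)."""
    g = ts.Geometry(alpha_e=0.2)
    b0 = BaselineSpec()
    b1 = BaselineSpec(V_n0=b0.V_n0 + 1.0)
    a0 = estimate_impermeants(b0, consts, g)[0]
    a1 = estimate_impermeants(b1, consts, g)[0]
    assert a1 - a0 == pytest.approx(-consts.C_n / consts.F, rel=1e-9)


def test_impermeants_balanced_toy_baseline(consts):
    """A zero-potential baseline with identical composition everywhere needs
    no impermeant ions at all."""
    g = ts.Geometry(W_n0=1.0, W_a0=1.0, alpha_e=0.5)
    b = BaselineSpec(V_n0=0.0, V_a0=0.0,
                     na_n0=10.0, k_n0=10.0, cl_n0=20.0,
                     na_a0=10.0, k_a0=10.0, cl_a0=20.0,
                     na_e0=10.0, k_e0=10.0, cl_e0=20.0,
                     ca_n0=1e-12, ca_a0=1e-12, ca_c0=1e-12,
                     glu_n0=1e-9, glu_a0=1e-9, glu_c0=1e-12,
                     N_D0=0, N_N0=0, N_R0=0, N_R10=0, N_R20=0, N_R30=0)
    imps = estimate_impermeants(b, consts, g)
    assert np.allclose(imps, 0.0, atol=1e-6)


def test_conserved_totals_roundtrip(model_small_ecs, consts):
    """Re-deriving the extracellular concentration from (C_X, intracellular
    amounts) returns the configured baseline exactly."""
    m = model_small_ecs
    view = ts.compartment_view(m.y0, m.totals, m.geom, m.consts)
    assert view.na_e == pytest.approx(m.baseline.na_e0, rel=1e-12)
    assert view.k_e == pytest.approx(m.baseline.k_e0, rel=1e-12)
    assert view.cl_e == pytest.approx(m.baseline.cl_e0, rel=1e-12)


def test_conserved_totals_values(model_small_ecs):
    t = model_small_ecs.totals
    # amounts follow from concentration * volume over all compartments
    assert t.C_Na == pytest.approx(13 * 2 + 13 * 2 + 152 * 1.0)
    assert t.C_Ca == pytest.approx(1.8e-3, rel=2e-4)
    assert t.C_Glu == pytest.approx(5e-3, rel=1e-3)
    assert t.C_W == pytest.approx(5.0)


def test_leak_permeabilities_match_reference(model_small_ecs):
    """Calibrated neuronal leaks agree with the reference resting budget
    (Cl- and glutamate to ~0.1%, the others to a few percent)."""
    tp = model_small_ecs.tp
    assert tp.P_L_Cl_n == pytest.approx(2.494e-6, rel=5e-4)
    assert tp.P_L_Glu_n == pytest.approx(3.662e-6, rel=5e-4)
    assert tp.P_L_Ca_n == pytest.approx(1.649e-11, rel=5e-3)
    assert tp.P_L_Na_n == pytest.approx(1.706e-6, rel=0.02)
    assert tp.P_L_K_n == pytest.approx(1.771e-5, rel=0.02)
    # all leaks are physical (non-negative)
    for x in ("Na", "K", "Cl", "Ca", "Glu"):
        for i in ("n", "a"):
            assert getattr(tp, f"P_L_{x}_{i}") >= 0.0


def test_leaks_independent_of_alpha_e(model_small_ecs, model_large_ecs):
    # leaks balance concentrations, which do not depend on the ECS size
    for x in ("Na", "K", "Cl", "Ca", "Glu"):
        for i in ("n", "a"):
            a = getattr(model_small_ecs.tp, f"P_L_{x}_{i}")
            b = getattr(model_large_ecs.tp, f"P_L_{x}_{i}")
            assert a == pytest.approx(b, rel=1e-9)


def test_baseline_is_equilibrium(model_small_ecs, model_large_ecs):
    for m in (model_small_ecs, model_large_ecs):
        assert baseline_residual(m) < 1e-9


def test_calibration_idempotent(model_small_ecs):
    m1 = model_small_ecs
    m2 = ts.calibrate(alpha_e=0.2)
    assert np.allclose(m1.y0, m2.y0, rtol=0, atol=0)
    assert m1.tp == m2.tp
    assert m1.vp.k_m2cat == m2.vp.k_m2cat


def test_nka_doubling_doubles_na_leak_residual(model_small_ecs):
    """The Na+ leak must offset (mostly) the pump: doubling the pump's
    contribution doubles the residual the leak absorbs (linearity)."""
    m = model_small_ecs
    zero = {f"P_L_{x}_{i}": 0.0 for x in ("Na", "K", "Cl", "Ca", "Glu")
            for i in ("n", "a")}
    tp0 = m.tp.copy(**zero)
    r1 = rhs_autonomous(m.y0, m.totals, m.geom, m.consts, tp0, m.vp, energy=1.0)
    tp2 = tp0.copy(P_scale=2.0)
    r2 = rhs_autonomous(m.y0, m.totals, m.geom, m.consts, tp2, m.vp, energy=1.0)
    # isolate the pump term: rhs difference is exactly the extra pump flux
    extra = r2 - r1
    assert extra[0] == pytest.approx(r1[0] - (r1[0] - extra[0]), rel=1e-12)
    assert extra[0] < 0  # additional Na efflux to be offset


def test_recalibrate_for_pscale(model_small_ecs):
    m = model_small_ecs
    m2 = ts.recalibrate_for_pscale(m, 2.0)
    assert np.allclose(m2.y0, m.y0)
    assert baseline_residual(m2) < 1e-9
    # identity at P_scale = 1
    m1 = ts.recalibrate_for_pscale(m, 1.0)
    assert m1.tp.P_L_Na_n == pytest.approx(m.tp.P_L_Na_n, rel=1e-12)
    with pytest.raises(ValueError):
        ts.recalibrate_for_pscale(m, 0.0)


def test_pscale_equilibrium_holds_in_simulation(model_small_ecs):
    """After pump rescaling and leak recomputation, a long simulation at full
    energy stays at baseline."""
    m2 = ts.recalibrate_for_pscale(model_small_ecs, 2.0)
    res = ts.integrate(m2, ts.Protocols(), t_end=60.0, coarse_dt_ms=2000.0)
    assert abs(res.series["V_n"][-1] + 65.5) < 1e-3
    drift = np.max(np.abs(res.y[:, -1] - m2.y0) / np.maximum(np.abs(m2.y0), 1e-12))
    assert drift < 1e-4


def test_backrate_calibration_value(model_small_ecs):
    vp = ts.VesicleParams()
    k = calibrate_vesicle_backrate(BaselineSpec(), vp)
    assert k == pytest.approx(model_small_ecs.vp.k_m2cat, rel=1e-12)


def test_infeasible_baseline_raises(consts):
    # an absurd baseline (astrocyte osmolarity far above ECS with tiny
    # potential) drives an impermeant amount negative
    b = BaselineSpec(k_a0=400.0, V_a0=-1.0)
    with pytest.raises(CalibrationError):
        ts.calibrate(alpha_e=0.2, baseline=b)
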