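"""Kinetic core: closed-form cascade solutions against ODE integration,
superposition/linearity invariants, and the derived steady-state
identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from citpk.structural import (
    COMPOUNDS,
    DoseEvent,
    RCIT,
    RDCT,
    SCIT,
    SDCT,
    StructuralParams,
    auc_at_steady_state,
    exp_dd2,
    exp_dd3,
    half_life,
    ode_rhs,
    once_daily_regimen,
    predict_analytic,
    predict_ode,
)

MALE_EMRM = dict(cl_rp=13.0, cl_sp=22.1, cl_rm=24.4, cl_sm=38.8,
                 v_r=1830.0, v_s=1390.0)


def test_ode_rhs_zero_state_is_equilibrium():
    p = StructuralParams(**MALE_EMRM)
    assert np.all(ode_rhs(np.zeros(6), p) == 0.0)


def test_ode_rhs_metabolite_formation_equals_parent_elimination():
    p = StructuralParams(**MALE_EMRM)
    state = np.array([0.0, 0.0, 0.05, 0.03, 0.0, 0.0])
    d = ode_rhs(state, p)
    assert d[4] == pytest.approx(p.cl_rp / p.v_r * state[2], rel=1e-14)
    assert d[5] == pytest.approx(p.cl_sp / p.v_s * state[3], rel=1e-14)
    # complete conversion: parent loss feeds the metabolite exactly
    assert d[2] == pytest.approx(-p.cl_rp / p.v_r * state[2], rel=1e-14)


def test_ode_rhs_rejects_nonfinite_state():
    p = StructuralParams(**MALE_EMRM)
    with pytest.raises(FloatingPointError):
        ode_rhs(np.array([np.nan, 0, 0, 0, 0, 0]), p)


def test_single_dose_analytic_matches_ode():
    p = StructuralParams(**MALE_EMRM)
    regimen = [DoseEvent(0.0, 30.0)]  # 15 mg per enantiomer depot
    times = np.linspace(0.5, 96.0, 40)
    ana = predict_analytic(regimen, p, times)
    ode = predict_ode(regimen, p, times)
    for c in COMPOUNDS:
        assert ana.conc[c] == pytest.approx(ode.conc[c], rel=1e-6)


def test_multidose_analytic_matches_ode():
    p = StructuralParams(**MALE_EMRM)
    regimen = once_daily_regimen([30.0] * 20)
    times = np.linspace(1.0, 20 * 24.0, 60)
    ana = predict_analytic(regimen, p, times)
    ode = predict_ode(regimen, p, times)
    for c in COMPOUNDS:
        assert ana.conc[c] == pytest.approx(ode.conc[c], rel=1e-5)


def test_analytic_ode_equivalence_on_random_parameters(rng):
    times = np.linspace(0.5, 120.0, 15)
    regimen = [DoseEvent(0.0, 20.0), DoseEvent(24.0, 40.0)]
    for _ in range(100):
        p = StructuralParams(
            cl_rp=rng.uniform(2, 60), cl_sp=rng.uniform(2, 60),
            cl_rm=rng.uniform(2, 80), cl_sm=rng.uniform(2, 80),
            v_r=rng.uniform(200, 4000), v_s=rng.uniform(200, 4000),
            ka=rng.uniform(0.3, 3.0),
        )
        ana = predict_analytic(regimen, p, times)
        ode = predict_ode(regimen, p, times, rtol=1e-11, atol=1e-13)
        for c in COMPOUNDS:
            np.testing.assert_allclose(ana.conc[c], ode.conc[c],
                                       rtol=1e-5, atol=1e-10)


def test_superposition_and_dose_linearity():
    p = StructuralParams(**MALE_EMRM)
    times = np.linspace(1.0, 200.0, 37)
    d1 = [DoseEvent(0.0, 30.0)]
    d2 = [DoseEvent(48.0, 30.0)]
    both = d1 + d2
    a1 = predict_analytic(d1, p, times)
    a2 = predict_analytic(d2, p, times)
    ab = predict_analytic(both, p, times)
    double = predict_analytic([DoseEvent(0.0, 60.0), DoseEvent(48.0, 60.0)], p, times)
    for c in COMPOUNDS:
        np.testing.assert_allclose(ab.conc[c], a1.conc[c] + a2.conc[c],
                                   rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(double.conc[c], 2.0 * ab.conc[c],
                                   rtol=1e-8, atol=1e-12)


def test_empty_regimen_gives_zero_profile():
    p = StructuralParams(**MALE_EMRM)
    prof = predict_analytic([], p, np.linspace(0, 48, 5))
    for c in COMPOUNDS:
        assert np.all(prof.conc[c] == 0.0)


def test_mass_balance_complete_conversion():
    """Depot + parent + metabolite + cumulative metabolite elimination
    accounts for the whole dose to 0.1%."""
    p = StructuralParams(**MALE_EMRM)
    dose = 30.0

    def rhs(t, state):
        base = ode_rhs(state[:6], p)
        elim_r = p.cl_rm / p.v_r * state[4] * p.v_r   # mg/h eliminated R-DCT
        elim_s = p.cl_sm / p.v_s * state[5] * p.v_s
        return np.concatenate([base, [elim_r, elim_s]])

    y0 = np.zeros(8)
    y0[0] = y0[1] = dose / 2
    sol = solve_ivp(rhs, (0, 500.0), y0, rtol=1e-10, atol=1e-12)
    s = sol.y[:, -1]
    total_r = s[0] + s[2] * p.v_r + s[4] * p.v_r + s[6]
    total_s = s[1] + s[3] * p.v_s + s[5] * p.v_s + s[7]
    assert total_r == pytest.approx(dose / 2, rel=1e-3)
    assert total_s == pytest.approx(dose / 2, rel=1e-3)


def test_steady_state_average_equals_dose_over_cl():
    """Time-averaged steady-state S-citalopram matches 15 mg / (CL*24h)."""
    p = StructuralParams(**MALE_EMRM)
    regimen = once_daily_regimen([30.0] * 40)
    tgrid = np.linspace(39 * 24.0, 40 * 24.0, 2001)
    prof = predict_analytic(regimen, p, tgrid)
    avg = np.trapezoid(prof.conc[SCIT], tgrid) / 24.0
    expected = 15.0 / (22.1 * 24.0) * 1000.0  # ~28.3 ng/mL
    assert avg == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize(
    "cl, v, expected, rel",
    [
        (22.1, 1390.0, 43.6, 0.01),    # S-parent EM/RM: the ~43 h half-life
        (13.0, 1830.0, 97.57, 0.001),  # R-parent male
        (1.0, 1.0, np.log(2.0), 1e-12),
    ],
)
def test_half_life_values(cl, v, expected, rel):
    assert half_life(cl, v) == pytest.approx(expected, rel=rel)


def test_half_life_matches_terminal_slope():
    p = StructuralParams(**MALE_EMRM)
    t = np.array([300.0, 400.0])
    prof = predict_analytic([DoseEvent(0.0, 30.0)], p, t)
    slope = (np.log(prof.conc[RCIT][1]) - np.log(prof.conc[RCIT][0])) / 100.0
    assert np.log(2.0) / -slope == pytest.approx(half_life(13.0, 1830.0), rel=1e-4)


def test_half_life_domain_errors():
    with pytest.raises(ValueError):
        half_life(0.0, 100.0)
    with pytest.raises(ValueError):
        half_life(10.0, -1.0)


def test_auc_identities():
    assert auc_at_steady_state(15.0, 15.0) == pytest.approx(1.0)
    assert auc_at_steady_state(15.0, 8.73) == pytest.approx(1.718, rel=1e-3)
    with pytest.raises(ValueError):
        auc_at_steady_state(15.0, 0.0)


def test_auc_ratio_metabolite_over_parent_is_clp_over_clm():
    """At steady state AUC_m/AUC_p = CL_p/CL_m (within 1% by trapezoid)."""
    p = StructuralParams(**MALE_EMRM)
    regimen = once_daily_regimen([30.0] * 60)
    tgrid = np.linspace(59 * 24.0, 60 * 24.0, 4001)
    prof = predict_analytic(regimen, p, tgrid)
    for parent, metab, clp, clm in [
        (RCIT, RDCT, 13.0, 24.4),
        (SCIT, SDCT, 22.1, 38.8),
    ]:
        ratio = (np.trapezoid(prof.conc[metab], tgrid)
                 / np.trapezoid(prof.conc[parent], tgrid))
        assert ratio == pytest.approx(clp / clm, rel=0.01)


def test_confluent_branches_are_continuous():
    t = np.linspace(0.1, 48.0, 20)
    k = 0.05
    eps = 1e-7  # just outside the switch tolerance
    np.testing.assert_allclose(
        exp_dd2(k, k * (1 + eps), t), exp_dd2(k, k, t), rtol=1e-5
    )
    np.testing.assert_allclose(
        exp_dd3(1.0, k, k * (1 + eps), t), exp_dd3(1.0, k, k, t), rtol=1e-4
    )
    np.testing.assert_allclose(
        exp_dd3(k, k * (1 + eps), k * (1 - eps), t),
        exp_dd3(k, k, k, t), rtol=1e-4,
    )


def test_equal_absorption_and_elimination_matches_ode():
    # ka == kp exactly: the confluent branch against the integrator
    p = StructuralParams(cl_rp=18.3, cl_sp=22.1, cl_rm=24.4, cl_sm=38.8,
                         v_r=1830.0, v_s=1390.0, ka=18.3 / 1830.0)
    times = np.linspace(1.0, 400.0, 25)
    ana = predict_analytic([DoseEvent(0.0, 30.0)], p, times)
    ode = predict_ode([DoseEvent(0.0, 30.0)], p, times)
    for c in COMPOUNDS:
        np.testing.assert_allclose(ana.conc[c], ode.conc[c], rtol=1e-5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    cl=st.floats(1.0, 80.0),
    v=st.floats(100.0, 5000.0),
    shift=st.floats(0.0, 48.0),
)
def test_profiles_nonnegative_and_zero_before_first_dose(cl, v, shift):
    p = StructuralParams(cl_rp=cl, cl_sp=cl, cl_rm=cl * 1.5, cl_sm=cl * 1.5,
                         v_r=v, v_s=v)
    times = np.linspace(0.0, shift + 96.0, 50)
    prof = predict_analytic([DoseEvent(shift, 30.0)], p, times)
    for c in COMPOUNDS:
        assert np.all(prof.conc[c] >= 0.0)
        assert np.all(prof.conc[c][times <= shift] == 0.0)


def test_validation_of_parameters_and_doses():
    with pytest.raises(ValueError):
        StructuralParams(cl_rp=-1, cl_sp=1, cl_rm=1, cl_sm=1, v_r=1, v_s=1)
    with pytest.raises(ValueError):
        DoseEvent(-1.0, 30.0)
    with pytest.raises(ValueError):
        DoseEvent(0.0, 0.0)
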