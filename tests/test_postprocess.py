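"""Diagnostics: CWRES calibration and degenerate limits, subgroup
summaries, exposures, and the Mann-Whitney contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from citpk.covariates import ThetaVector
from citpk.defaults import final_theta
from citpk.population import OmegaSpec
from citpk.postprocess import (
    cwres,
    exposure_summary,
    individual_parameters,
    mann_whitney,
    subgroup_summary,
)
from citpk.structural import auc_at_steady_state, once_daily_regimen, predict_analytic

ZERO_OMEGA = OmegaSpec(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def test_cwres_collapses_to_wres_without_bsv(small_trial, theta, sigma):
    """With omega = 0 the conditional residuals equal (DV - PRED)/sd."""
    ds, _ = small_trial
    tab = cwres(ds, theta, ZERO_OMEGA, sigma)
    from citpk.population import residual_sd

    for _, row in tab.iterrows():
        sd = residual_sd(row["PRED"], row["compound"], sigma)
        assert row["CWRES"] == pytest.approx(
            (row["DV"] - row["PRED"]) / sd, rel=1e-10
        )


def test_cwres_calibrated_under_the_true_model(trial, theta, omega, sigma):
    """Model == truth: CWRES approximately standard normal."""
    ds, _ = trial
    tab = cwres(ds, theta, omega, sigma)
    assert np.isfinite(tab["CWRES"]).all()
    assert abs(tab["CWRES"].mean()) < 0.08
    assert 0.85 < tab["CWRES"].var() < 1.2


def test_cwres_detects_direction_of_clearance_misfit(trial, theta, omega, sigma):
    """Halving the model's clearances doubles its predictions, so the
    observed data sit below them and the CWRES mean goes negative."""
    ds, _ = trial
    halved = ThetaVector(**{
        **theta.__dict__,
        "cl_rp_male": theta.cl_rp_male / 2, "cl_rp_female": theta.cl_rp_female / 2,
        "cl_sp_emrm": theta.cl_sp_emrm / 2, "cl_sp_impm": theta.cl_sp_impm / 2,
        "cl_sp_missing": theta.cl_sp_missing / 2,
        "cl_rm0": theta.cl_rm0 / 2, "cl_sm0": theta.cl_sm0 / 2,
    })
    good = cwres(ds, theta, omega, sigma)["CWRES"].mean()
    bad = cwres(ds, halved, omega, sigma)["CWRES"].mean()
    assert bad < good
    assert bad < -0.5


def test_individual_parameters_and_derived_half_lives(small_trial, theta, omega, sigma):
    ds, _ = small_trial
    indiv = individual_parameters(ds, theta, omega, sigma)
    assert len(indiv) == ds["ID"].nunique()
    assert (indiv[["cl_rp", "cl_sp", "cl_rm", "cl_sm"]] > 0).all().all()
    row = indiv.iloc[3]
    assert row["thalf_r"] == pytest.approx(np.log(2) * row["v_r"] / row["cl_rp"])


def test_subgroup_single_group_is_grand_mean(trial, theta, omega, sigma):
    ds, truth = trial
    table = truth.rename(columns={"AGE": "age", "WT": "weight", "BMI": "bmi",
                                  "SEX": "sex", "GEN": "genotype"})
    s = subgroup_summary(table.assign(age=50.0), "cl_rp", "age_band")
    assert len(s.groups) == 1
    assert s.groups["mean"].iloc[0] == pytest.approx(table["cl_rp"].mean())
    assert s.contrasts.empty


def test_subgroup_sex_and_weight_orderings(trial, theta, omega, sigma):
    """EBE-based summaries reproduce the final model's structure: males
    clear R-citalopram faster, heavier subjects clear the metabolites
    faster."""
    ds, _ = trial
    indiv = individual_parameters(ds, theta, omega, sigma)
    sex = subgroup_summary(indiv, "cl_rp", "sex")
    assert (sex.groups.loc["male", "mean"] > sex.groups.loc["female", "mean"])
    assert sex.contrasts.iloc[0]["faster"] == "male"
    wt = subgroup_summary(indiv, "cl_rm", "weight_band")
    assert wt.groups.loc[">=70kg", "mean"] > wt.groups.loc["<70kg", "mean"]
    # magnitudes in the neighbourhood of the reported EBE band means
    assert wt.groups.loc["<70kg", "mean"] == pytest.approx(20.14, rel=0.2)
    assert wt.groups.loc[">=70kg", "mean"] == pytest.approx(29.12, rel=0.2)


def test_subgroup_percent_difference_arithmetic():
    table = pd.DataFrame({
        "age": [60, 60, 80, 80], "weight": [70] * 4, "bmi": [25] * 4,
        "sex": [0, 0, 0, 0], "genotype": [1] * 4,
        "value": [27.6 * 2, 27.6 * 2, 20.0 * 2, 20.0 * 2],
    })
    s = subgroup_summary(table, "value", "age_band")
    c = s.contrasts.iloc[0]
    assert c["faster"] == "<70"
    assert c["percent_faster"] == pytest.approx(100 * (27.6 - 20.0) / 20.0)


def test_exposure_summary_formula_and_ordering(trial, theta, omega, sigma):
    ds, _ = trial
    indiv = individual_parameters(ds, theta, omega, sigma)
    out = exposure_summary(indiv, daily_racemic_dose=30.0)
    out = out.set_index("compound")
    # AUC = dose/CL identity per subject
    assert out.loc["R-citalopram", "mean_auc_mg_h_L"] == pytest.approx(
        (15.0 / indiv["cl_rp"]).mean(), rel=1e-12
    )
    # slower R clearance -> higher R exposure, significantly so
    assert (out.loc["R-citalopram", "mean_auc_mg_h_L"]
            > out.loc["S-citalopram", "mean_auc_mg_h_L"])
    assert out.loc["R-citalopram", "p_R_vs_S_parent"] < 0.05


def test_exposure_trivial_value():
    indiv = pd.DataFrame({"cl_rp": [15.0], "cl_sp": [15.0],
                          "cl_rm": [15.0], "cl_sm": [15.0]})
    out = exposure_summary(indiv, daily_racemic_dose=30.0).set_index("compound")
    assert out.loc["R-citalopram", "mean_auc_mg_h_L"] == pytest.approx(1.0)


def test_auc_formula_matches_trapezoid_at_steady_state(theta):
    from citpk.structural import SCIT, StructuralParams

    p = StructuralParams(cl_rp=13.0, cl_sp=22.1, cl_rm=24.4, cl_sm=38.8,
                         v_r=1830.0, v_s=1390.0)
    reg = once_daily_regimen([30.0] * 50)
    tgrid = np.linspace(49 * 24.0, 50 * 24.0, 3001)
    prof = predict_analytic(reg, p, tgrid)
    numeric = np.trapezoid(prof.conc[SCIT], tgrid) / 1000.0  # mg*h/L
    assert numeric == pytest.approx(auc_at_steady_state(15.0, 22.1), rel=0.01)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def test_mann_whitney_exact_enumeration_example():
    u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 two-sided


def test_mann_whitney_identical_pooled_values():
    u, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
    assert u == 3.0  # n1*n2/2
    assert p == 1.0


def test_mann_whitney_exact_close_to_normal_approximation(rng):
    a = rng.normal(0.0, 1.0, 8)
    b = rng.normal(0.5, 1.0, 8)
    _, p_exact = mann_whitney(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert abs(p_exact - res.pvalue) < 0.02


def test_mann_whitney_on_simulated_enantiomer_clearances(trial, theta, omega, sigma):
    ds, truth = trial
    _, p = mann_whitney(truth["cl_rp"].to_numpy(), truth["cl_sp"].to_numpy())
    assert p < 0.05  # R clears significantly slower than S


def test_mann_whitney_requires_nonempty_groups():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])
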