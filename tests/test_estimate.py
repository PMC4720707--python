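"""FOCE-I machinery: conjugate-Gaussian closed forms, exactness on
linear mixed models, empirical Bayes behaviour, fitting, selection
mechanics and the bootstrap contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from citpk.defaults import (
    default_demographics,
    default_design,
    final_omega,
    final_sigma,
    final_theta,
)
from citpk.estimate import (
    Candidate,
    ContinuousEffect,
    ModelVariant,
    _BatchProblem,
    _PopModel,
    _make_predict,
    bootstrap,
    build_parameters,
    ebe,
    estimate_eta,
    fit,
    foce_objective,
    init_from_estimates,
    laplace_ofv,
    prepare_subjects,
    retention_threshold,
    stepwise_select,
)
from citpk.io import split_by_subject
from citpk.simulate import simulate_trial


def _const_sigma(sd):
    def fn(pred):
        s = np.full(np.shape(pred), float(sd))
        return s, np.zeros_like(s)
    return fn


# ---------------------------------------------------------------------------
# inner problem oracles
# ---------------------------------------------------------------------------


def test_no_observations_reduces_to_prior_minimized_at_zero():
    omega = np.diag([0.1, 0.2])
    y = np.zeros(0)
    res = estimate_eta(y, lambda e: np.zeros(0), _const_sigma(1.0), omega)
    np.testing.assert_allclose(res.eta, 0.0, atol=1e-12)


def test_single_observation_conjugate_gaussian_mode():
    """Linear one-parameter toy: the posterior mode has the ridge
    closed form (g*r/sigma^2) / (g^2/sigma^2 + 1/omega^2)."""
    g, sd, om2, yobs, f0 = 2.5, 0.7, 0.09, 4.0, 1.0
    predict = lambda e: np.array([f0 + g * e[0]])
    res = estimate_eta(np.array([yobs]), predict, _const_sigma(sd),
                       np.array([[om2]]))
    r = yobs - f0
    expected = (g * r / sd**2) / (g**2 / sd**2 + 1.0 / om2)
    assert res.eta[0] == pytest.approx(expected, abs=1e-8)


def test_diffuse_prior_limit_is_least_squares(rng):
    g = rng.normal(size=(8, 2))
    eta_true = np.array([0.4, -0.3])
    y = g @ eta_true + rng.normal(0, 0.1, 8)
    res = estimate_eta(y, lambda e: g @ e, _const_sigma(0.5),
                       np.eye(2) * 1e8)
    ls = np.linalg.lstsq(g, y, rcond=None)[0]
    np.testing.assert_allclose(res.eta, ls, atol=1e-5)


def test_foce_objective_exact_on_linear_mixed_model(rng):
    """The decisive oracle: on models linear in eta with constant
    residual SD, the FOCE-I OFV equals the exact Gaussian marginal
    -2 log likelihood."""
    total = 0.0
    exact = 0.0
    omega = np.array([[0.09, 0.02], [0.02, 0.2]])
    sd = 0.8
    for _ in range(6):
        n = rng.integers(2, 7)
        g = rng.normal(size=(n, 2))
        a = rng.normal(size=n)
        y = a + g @ rng.multivariate_normal([0, 0], omega) + rng.normal(0, sd, n)
        ofv, _ = laplace_ofv(y, lambda e, g=g, a=a: a + g @ e,
                             _const_sigma(sd), omega)
        total += ofv
        cov = g @ omega @ g.T + np.eye(n) * sd**2
        exact += -2.0 * stats.multivariate_normal(mean=a, cov=cov).logpdf(y)
    assert total == pytest.approx(exact, rel=1e-6)


def test_full_laplace_hessian_also_exact_on_linear_model(rng):
    omega = np.diag([0.1, 0.3])
    g = rng.normal(size=(5, 2))
    a = rng.normal(size=5)
    y = a + rng.normal(0, 0.5, 5)
    gn, _ = laplace_ofv(y, lambda e: a + g @ e, _const_sigma(0.5), omega,
                        hessian="gauss-newton")
    full, _ = laplace_ofv(y, lambda e: a + g @ e, _const_sigma(0.5), omega,
                          hessian="full")
    assert gn == pytest.approx(full, rel=1e-5)


def test_duplicating_every_subject_doubles_ofv(small_trial, theta, omega, sigma):
    ds, _ = small_trial
    records = split_by_subject(ds)
    one = foce_objective(records, theta, omega, sigma)
    two = foce_objective(records + records, theta, omega, sigma)
    assert two == pytest.approx(2.0 * one, rel=1e-10)


def test_batched_solver_matches_per_subject_path(small_trial, theta, omega, sigma):
    """The vectorized population solver and the scalar per-subject
    Laplace path agree to near machine precision."""
    ds, _ = small_trial
    variant = ModelVariant.final_r()
    pars = build_parameters(variant, init_from_estimates(variant, theta, omega, sigma))
    model = _PopModel(variant, {p.name: p.init for p in pars})
    subs = [s for s in prepare_subjects(ds, "R") if s.n_obs > 0]
    bp = _BatchProblem(subs)
    typ = np.array([model.typical(s.cov) for s in subs])
    sig_add = np.where(bp.is_metab, 0.0, model.sig_parent)
    sig_prop = np.where(bp.is_metab, model.sig_metab, 0.0)
    total, _, _ = bp.solve(typ[:, 0], typ[:, 1], typ[:, 2], 0.0,
                           sig_add, sig_prop, model.omega)
    ref = 0.0
    for s in subs:
        clp, v, clm, clx = model.typical(s.cov)
        ofv_i, _ = laplace_ofv(s.y, _make_predict(s, clp, v, clm, clx, 1.0),
                               model.sigma_fn(s.is_metab), model.omega)
        ref += ofv_i
    assert total == pytest.approx(ref, rel=1e-10)


# ---------------------------------------------------------------------------
# empirical Bayes estimates
# ---------------------------------------------------------------------------


def test_inner_objective_minimized_at_the_ebe(small_trial, theta, omega, sigma):
    """The posterior mode found by `ebe` beats eta = 0 and nearby
    perturbations on the exact conditional -2 log joint density."""
    from citpk.estimate import inner_objective

    ds, _ = small_trial
    rec = split_by_subject(ds)[2]
    res = ebe(rec, theta, omega, sigma)
    at_mode = inner_objective(rec, res.eta, theta, omega, sigma)
    assert at_mode <= inner_objective(rec, np.zeros(6), theta, omega, sigma)
    rng = np.random.default_rng(0)
    for _ in range(5):
        assert at_mode <= inner_objective(
            rec, res.eta + rng.normal(0, 0.05, 6), theta, omega, sigma
        ) + 1e-9


def test_ebe_zero_observation_subject_returns_zero(trial, theta, omega, sigma):
    ds, _ = trial
    rec = split_by_subject(ds)[0]
    rec.obs_times = rec.obs_times[:0]
    rec.obs_compound = rec.obs_compound[:0]
    rec.dv = rec.dv[:0]
    rec.blq = rec.blq[:0]
    res = ebe(rec, theta, omega, sigma)
    np.testing.assert_allclose(res.eta, 0.0, atol=1e-12)


def test_ebe_recovers_eta_on_rich_data(theta, omega, sigma):
    """A densely sampled subject (50 observations) pins down its etas."""
    from citpk.covariates import SubjectCovariates
    from citpk.estimate import SubjectData
    from citpk.population import realize_individual, residual_sd
    from citpk.simulate import build_regimen
    from citpk.structural import predict_analytic

    rng = np.random.default_rng(123)
    cov = SubjectCovariates(age=75, weight=70, bmi=26, sex=0, cyp2c19_group=1)
    eta_true = np.array([0.2, -0.3, 0.15])  # R: clp, v, clm
    eta6 = np.concatenate([eta_true, np.zeros(3)])
    indiv = realize_individual(cov, theta, eta6)
    reg = build_regimen(default_design())
    # early (absorption/accumulation) times inform V; later ones inform CL
    times = np.sort(np.concatenate([
        rng.uniform(1.0, 96.0, 15), rng.uniform(96.0, 24.0 * 63, 35)
    ]))
    prof = predict_analytic(reg, indiv, times)
    dose_t = np.array([d.time for d in reg])
    dose_a = np.array([d.racemic_amount / 2 for d in reg])
    obs_t, is_m, y = [], [], []
    for compound, metab in [("RCIT", False), ("RDCT", True)]:
        for t, c in zip(times, prof.conc[compound]):
            obs_t.append(t)
            is_m.append(metab)
            y.append(c + rng.normal(0, residual_sd(c, compound, sigma)))
    sub = SubjectData(1, cov, dose_t, dose_a, np.array(obs_t),
                      np.array(is_m), np.array(y))
    from citpk.covariates import typical_params

    typ = typical_params(cov, theta)
    predict = _make_predict(sub, typ.cl_rp, typ.v_r, typ.cl_rm, 0.0, 1.0)
    variant = ModelVariant.final_r()
    model = _PopModel(variant, {
        p.name: p.init for p in build_parameters(
            variant, init_from_estimates(variant, theta, omega, sigma))
    })
    res = estimate_eta(sub.y, predict, model.sigma_fn(sub.is_metab), model.omega)
    np.testing.assert_allclose(res.eta, eta_true, atol=0.06)


def test_ebe_shrinkage_on_sparse_cohort(trial, theta, omega, sigma):
    """Sparse-data eta-hats are shrunk: their SD is below omega."""
    ds, _ = trial
    variant = ModelVariant.final_r()
    f = fit(ds, variant,
            init=init_from_estimates(variant, theta, omega, sigma),
            maxiter=0)  # evaluation at the published values, no refit
    sd_clp = f.etas["eta_clp"].std()
    assert sd_clp < np.sqrt(omega.var_cl_rp)
    sd_clm = f.etas["eta_clm"].std()
    assert sd_clm < np.sqrt(omega.var_cl_rm)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_fit_smoke_recovers_magnitudes(small_trial, theta, omega, sigma):
    ds, _ = small_trial
    variant = ModelVariant.final_s()
    f = fit(ds, variant, init=init_from_estimates(variant, theta, omega, sigma),
            maxiter=60)
    assert f.success
    assert np.isfinite(f.ofv)
    # sanity band, not a recovery claim, at n=25
    assert 0.4 * 22.1 < f.params["clp_emrm"] < 2.5 * 22.1
    assert np.linalg.eigvalsh(f.omega).min() > 0


def test_zero_bsv_limit_equals_fixed_effects_neg2ll(small_trial, theta, omega, sigma):
    """As omega -> 0 the subject OFV collapses to the eta=0 Gaussian
    -2 log likelihood (the log-determinant corrections cancel)."""
    ds, _ = small_trial
    subs = [s for s in prepare_subjects(ds, "R") if s.n_obs > 0]
    variant = ModelVariant.final_r()
    model = _PopModel(variant, {
        p.name: p.init for p in build_parameters(
            variant, init_from_estimates(variant, theta, omega, sigma))
    })
    tiny = np.eye(3) * 1e-12
    total = 0.0
    ref = 0.0
    for s in subs[:10]:
        clp, v, clm, clx = model.typical(s.cov)
        predict = _make_predict(s, clp, v, clm, clx, 1.0)
        ofv_i, _ = laplace_ofv(s.y, predict, model.sigma_fn(s.is_metab), tiny)
        total += ofv_i
        pred = predict(np.zeros(3))
        sd, _ = model.sigma_fn(s.is_metab)(pred)
        ref += float(np.sum(np.log(2 * np.pi * sd**2) + ((s.y - pred) / sd) ** 2))
    assert total == pytest.approx(ref, rel=1e-6)


def test_unsupported_structural_variants_refused(small_trial):
    ds, _ = small_trial
    with pytest.raises(NotImplementedError):
        fit(ds, ModelVariant(enantiomer="R", parent_compartments=2))
    with pytest.raises(NotImplementedError):
        fit(ds, ModelVariant(enantiomer="R", direct_metabolite_dosing=True))


def test_partial_conversion_variant_is_fittable(small_trial):
    ds, _ = small_trial
    v = ModelVariant(enantiomer="R", conversion="partial")
    f = fit(ds, v, maxiter=12)
    assert "clx" in f.params and f.params["clx"] > 0


def test_true_residual_structure_beats_swapped_one(small_trial):
    """Likelihood dominance: the generating residual structure (additive
    R parent, proportional metabolite) attains lower OFV than the
    swapped misspecification on data it generated."""
    ds, _ = small_trial
    good = fit(ds, ModelVariant.base_r(), maxiter=50)
    swapped = fit(
        ds,
        ModelVariant(enantiomer="R", residual_parent="proportional",
                     residual_metabolite="additive"),
        maxiter=50,
    )
    assert good.ofv < swapped.ofv


def test_monotone_nesting_adding_a_parameter_never_hurts(small_trial):
    ds, _ = small_trial
    base = fit(ds, ModelVariant.base_r(), maxiter=50)
    with_bmi = fit(
        ds,
        Candidate(effect=ContinuousEffect("clp", "bmi", "power")).added_to(
            ModelVariant.base_r()),
        init=dict(base.params), maxiter=50,
    )
    assert with_bmi.ofv <= base.ofv + 0.1


# ---------------------------------------------------------------------------
# stepwise selection and bootstrap
# ---------------------------------------------------------------------------


def test_retention_thresholds_match_chi_square_quantiles():
    assert retention_threshold(1) == pytest.approx(3.84, abs=0.005)
    assert retention_threshold(2) == pytest.approx(5.99, abs=0.005)


def test_candidate_moves_and_df():
    base = ModelVariant.base_r()
    age = Candidate(effect=ContinuousEffect("clp", "age", "power"))
    sex = Candidate(split="sex")
    gen = Candidate(split="genotype")
    assert age.df == 1 and sex.df == 1 and gen.df == 2
    v = age.added_to(base)
    assert age.applies_to(base) and not age.applies_to(v)
    assert sex.added_to(base).clp_split == "sex"
    assert age.removed_from(v).effects == ()
    with pytest.raises(ValueError):
        Candidate()


def test_stepwise_select_trace_and_threshold_logic(small_trial):
    """Forward selection adds the best candidate only when the OFV drop
    clears the chi-square threshold, and the trace records every trial
    fit; backward elimination never removes a covariate whose removal
    raises the OFV by at least the threshold."""
    ds, _ = small_trial
    candidates = [
        Candidate(effect=ContinuousEffect("clp", "age", "power")),
        Candidate(effect=ContinuousEffect("clp", "bmi", "power")),
    ]
    sel = stepwise_select(ds, ModelVariant.base_r(), candidates,
                          fit_kwargs={"maxiter": 30})
    t = sel.trace
    assert set(t["phase"]) <= {"forward", "backward"}
    tried = t[t["action"] == "tried"]
    added = t[t["action"] == "added"]
    thr = retention_threshold(1)
    for _, row in added.iterrows():
        assert row["delta_ofv"] >= thr
        step_trials = tried[tried["step"] == row["step"]]
        assert row["delta_ofv"] == pytest.approx(step_trials["delta_ofv"].max())
    # anything surviving backward elimination costs >= the threshold to drop
    removals = t[t["action"] == "tried-removal"]
    surviving = {c.label for c in sel.included}
    if len(removals):
        last_step = removals["step"].max()
        final_round = removals[removals["step"] == last_step]
        kept = final_round[final_round["candidate"].isin(surviving)]
        assert (kept["delta_ofv"] >= retention_threshold(1) - 1e-9).all()
    # the final variant contains exactly the retained candidates
    names = {e.name for e in sel.final_variant.effects}
    assert names == {c.effect.name for c in sel.included}


def test_bootstrap_contract(small_trial, theta, omega, sigma):
    ds, _ = small_trial
    variant = ModelVariant.final_r()
    init = init_from_estimates(variant, theta, omega, sigma)
    a = bootstrap(ds, variant, seed=5, n_replicates=4, init=init,
                  fit_kwargs={"maxiter": 15})
    b = bootstrap(ds, variant, seed=5, n_replicates=2, init=init,
                  fit_kwargs={"maxiter": 15})
    # same seed -> the shared leading replicates are drawn and fit identically
    pd.testing.assert_frame_equal(a.replicates.head(len(b.replicates)),
                                  b.replicates)
    assert len(a.replicates) + a.n_failed == 4
    assert {"median", "ci_lo", "ci_hi"} == set(a.summary.columns)
    assert (a.summary["ci_lo"] <= a.summary["median"]).all()
    assert (a.summary["median"] <= a.summary["ci_hi"]).all()
    assert a.status in ("ok", "warning")
    with pytest.raises(TypeError):
        bootstrap(ds, variant, seed=None)
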