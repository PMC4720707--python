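"""Simulation-study drivers: simulate-and-refit, population summaries,
and covariate-selection operating characteristics.

These functions define the study conditions used throughout the package
(trial size 81, the published parameters as generating truth) and are
shared by the analysis scripts, the acceptance checks and the heavier
tests.  All randomness flows from an explicit integer seed through
``numpy.random.SeedSequence`` spawning, so every experiment is exactly
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import typical_cl_rp, typical_cl_sp
from .defaults import (
    default_demographics,
    default_design,
    final_omega,
    final_sigma,
    final_theta,
)
from .estimate import (
    Candidate,
    ContinuousEffect,
    ModelVariant,
    fit,
    init_from_estimates,
    retention_threshold,
)
from .population import sample_eta
from .simulate import sample_demographics, simulate_trial

__all__ = [
    "child_seeds",
    "simulate_refit_experiment",
    "population_clearance_means",
    "selection_experiment",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def simulate_refit_experiment(
    n_trials: int = 5,
    seed: int = 1,
    n_subjects: int = 81,
    maxiter: int = 150,
    enantiomers: tuple[str, ...] = ("R", "S"),
) -> pd.DataFrame:
    """Simulate trials under the final published model and refit them.

    Each trial uses the study design (sparse sampling at weeks 3/6/9
    with LOQ censoring) and the published demographics; the final-model
    structure is refitted per enantiomer by FOCE-I starting from the
    generating values.  Returns one row per trial with the recovered
    fixed effects.
    """
    theta, omega, sigma = final_theta(), final_omega(), final_sigma()
    design = default_design()
    design.n_subjects = n_subjects
    demo = default_demographics()
    rows = []
    for trial, s in enumerate(child_seeds(seed, n_trials)):
        ds, _truth = simulate_trial(design, demo, theta, omega, sigma, seed=s)
        row = {"trial": trial, "seed": s}
        if "R" in enantiomers:
            vr = ModelVariant.final_r()
            fr = fit(ds, vr, init=init_from_estimates(vr, theta, omega, sigma),
                     maxiter=maxiter, compute_etas=False)
            row.update(
                clp_male=fr.params["clp_male"],
                clp_female=fr.params["clp_female"],
                age_exp_r=fr.params["clp_age_exp"],
                clm_r=fr.params["clm"],
                ofv_r=fr.ofv, success_r=fr.success,
            )
        if "S" in enantiomers:
            vs = ModelVariant.final_s()
            fs = fit(ds, vs, init=init_from_estimates(vs, theta, omega, sigma),
                     maxiter=maxiter, compute_etas=False)
            row.update(
                clp_emrm=fs.params["clp_emrm"],
                clp_impm=fs.params["clp_impm"],
                age_exp_s=fs.params["clp_age_exp"],
                clm_s=fs.params["clm"],
                ofv_s=fs.ofv, success_s=fs.success,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def population_clearance_means(n: int = 2000, seed: int = 1) -> dict[str, float]:
    """Mean realized parent clearances in a simulated population.

    Subjects are drawn from the published demographics, etas from the
    published Omega; each subject's realized CL is the covariate-typical
    value times exp(eta).  Returns the population means (L/h).
    """
    theta, omega = final_theta(), final_omega()
    demo = default_demographics()
    s_demo, s_eta = child_seeds(seed, 2)
    covs = sample_demographics(demo, n, s_demo)
    etas = sample_eta(omega, n, s_eta)
    cl_rp = np.array(
        [typical_cl_rp(c, theta) for c in covs]
    ) * np.exp(etas[:, 0])
    cl_sp = np.array(
        [typical_cl_sp(c, theta) for c in covs]
    ) * np.exp(etas[:, 3])
    return {
        "mean_cl_rp": float(cl_rp.mean()),
        "mean_cl_sp": float(cl_sp.mean()),
        "n": n,
    }


def selection_experiment(
    n_trials: int = 20,
    seed: int = 1,
    n_subjects: int = 81,
    maxiter: int = 100,
) -> pd.DataFrame:
    """Operating characteristics of the forward OFV-drop rule.

    Each trial is simulated under the final model (which carries a true
    age effect on R-citalopram clearance of the published magnitude and
    no BMI effect anywhere).  Mirroring the staged model build, the
    candidate steps are evaluated on the R-citalopram parent-only model:
    from the covariate-free base, the age and BMI power effects on CL_Rp
    are each tried as a univariate forward step; retention means the OFV
    drops by at least the chi-square threshold (3.84 at one degree of
    freedom).  Age retention estimates power, BMI retention the type-I
    rate.

    Likelihood-ratio hygiene: the surface is multimodal, so whenever an
    augmented fit lands more than the threshold below the base, the base
    is refit warm-started from the augmented solution with the covariate
    removed; the ratio always compares the best optimum found for each
    model, preventing optimizer escapes from masquerading as covariate
    signal.
    """
    theta, omega, sigma = final_theta(), final_omega(), final_sigma()
    design = default_design()
    design.n_subjects = n_subjects
    demo = default_demographics()
    thr = retention_threshold(1)
    rows = []
    for trial, s in enumerate(child_seeds(seed, n_trials)):
        ds, _ = simulate_trial(design, demo, theta, omega, sigma, seed=s)
        base = ModelVariant.base_r()
        base = type(base)(**{**base.__dict__, "include_metabolite": False})
        f0 = fit(ds, base, maxiter=maxiter, compute_etas=False)
        base_ofv = f0.ofv
        init0 = dict(f0.params)
        fits = {}
        for cov_name in ("age", "bmi"):
            cand = Candidate(effect=ContinuousEffect("clp", cov_name, "power"))
            v2 = cand.added_to(base)
            f2 = fit(ds, v2, init=init0, maxiter=maxiter, compute_etas=False)
            fits[cov_name] = f2
        # hygiene refits of the base from each escaping augmented solution
        for cov_name, f2 in fits.items():
            if base_ofv - f2.ofv >= thr:
                init_back = {k: val for k, val in f2.params.items()
                             if not k.startswith("clp_") or k in
                             ("clp_male", "clp_female", "clp_emrm",
                              "clp_impm", "clp_missing")}
                init_back.pop(f"clp_{cov_name}_exp", None)
                fb = fit(ds, base, init={**dict(f2.params), **init_back},
                         maxiter=maxiter, compute_etas=False)
                base_ofv = min(base_ofv, fb.ofv)
        deltas = {k: base_ofv - f.ofv for k, f in fits.items()}
        rows.append(
            {
                "trial": trial,
                "seed": s,
                "delta_age": deltas["age"],
                "delta_bmi": deltas["bmi"],
                "age_retained": deltas["age"] >= thr,
                "bmi_retained": deltas["bmi"] >= thr,
            }
        )
    return pd.DataFrame(rows)
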