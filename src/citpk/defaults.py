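"""Reference parameter values and study-design defaults.

These are the final published population estimates for elderly
Alzheimer's disease patients on racemic citalopram, together with the
trial design (2-week titration to 30 mg once daily, sparse sampling at
weeks 3/6/9) and the cohort demographics they were estimated from.  The
simulation study in this package uses them as the generating truth.
"""

from __future__ import annotations

from .covariates import ThetaVector
from .population import OmegaSpec, SigmaSpec
from .simulate import DemographicsModel, TrialDesign

__all__ = [
    "final_theta",
    "final_omega",
    "final_sigma",
    "base_init_theta",
    "default_design",
    "default_demographics",
]


def final_theta() -> ThetaVector:
    """Final-model fixed effects (apparent clearances L/h, volumes L)."""
    return ThetaVector(
        cl_rp_male=13.0,
        cl_rp_female=9.05,
        age_exp_r=-0.822,
        v_r=1830.0,
        cl_rm0=24.4,
        cl_sp_emrm=22.1,
        cl_sp_impm=16.3,
        cl_sp_missing=16.8,
        age_exp_s=-1.33,
        v_s=1390.0,
        cl_sm0=38.8,
        wt_exp=0.75,
        ka=1.0,
    )


def final_omega() -> OmegaSpec:
    """Final-model BSV, from the percent (100*sqrt(variance)) reporting."""
    return OmegaSpec.from_percent(
        cl_rp=26.38,
        v_r=166.73,
        cl_rm=30.61,
        cl_sp=38.34,
        v_s=75.37,
        cov_cl_v_s=47.1,
        cl_sm=20.49,
    )


def final_sigma() -> SigmaSpec:
    """Final-model residual error: additive 13.42 ng/mL for R-citalopram,
    proportional 21.54% for R-desmethylcitalopram, shared proportional
    21.61% for the S compounds."""
    return SigmaSpec(
        rcit_additive_sd=13.42,
        rdct_prop_sd=0.2154,
        s_prop_sd=0.2161,
    )


def base_init_theta() -> ThetaVector:
    """Covariate-free base-model magnitudes, used as fit initial values."""
    return ThetaVector(
        cl_rp_male=8.6,
        cl_rp_female=8.6,
        age_exp_r=0.0,
        v_r=2050.0,
        cl_rm0=23.8,
        cl_sp_emrm=14.0,
        cl_sp_impm=14.0,
        cl_sp_missing=14.0,
        age_exp_s=0.0,
        v_s=1450.0,
        cl_sm0=38.5,
        wt_exp=0.75,
        ka=1.0,
    )


def default_design() -> TrialDesign:
    return TrialDesign()


def default_demographics() -> DemographicsModel:
    return DemographicsModel()
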