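"""Covariate model: subject characteristics -> typical parameter values.

The final covariate model found for this elderly Alzheimer's disease
population on racemic citalopram is:

* R-citalopram apparent metabolic clearance: sex-specific base value
  times a centered power of age, ``CL_Rp/F = CL0/F * (age/60)^-0.822``.
* S-citalopram apparent metabolic clearance: CYP2C19-group-specific base
  value times centered powers of age (exponent -1.33) and body weight
  (allometric exponent 0.75).
* Both desmethyl metabolite clearances: base value times
  ``(weight/70)^0.75``.
* Volumes of distribution and ka carry no covariates.

Age is centered at 60 years and weight at 70 kg, so every covariate
factor equals exactly 1 at the centering values.  BMI was evaluated
during model building but retained nowhere; typical values are invariant
to it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structural import StructuralParams

__all__ = [
    "AGE_CENTER",
    "WT_CENTER",
    "BMI_CENTER",
    "SEX_MALE",
    "SEX_FEMALE",
    "GEN_EMRM",
    "GEN_IMPM",
    "GEN_MISSING",
    "SubjectCovariates",
    "ThetaVector",
    "covariate_factor",
    "typical_cl_rp",
    "typical_cl_sp",
    "typical_cl_m",
    "typical_params",
    "sex_contrast",
]

AGE_CENTER = 60.0
WT_CENTER = 70.0
BMI_CENTER = 25.0

SEX_MALE = 0
SEX_FEMALE = 1

# CYP2C19 metabolizer groups: extensive/rapid, intermediate/poor, missing
GEN_EMRM = 1
GEN_IMPM = 2
GEN_MISSING = 3


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates feeding the typical-value equations (constant in time)."""

    age: float
    weight: float
    bmi: float
    sex: int
    cyp2c19_group: int

    def __post_init__(self) -> None:
        if not self.age > 18:
            raise ValueError(f"age must be a plausible adult age, got {self.age}")
        if not self.weight > 0:
            raise ValueError("weight must be > 0 kg")
        if self.sex not in (SEX_MALE, SEX_FEMALE):
            raise ValueError("sex must be 0 (male) or 1 (female)")
        if self.cyp2c19_group not in (GEN_EMRM, GEN_IMPM, GEN_MISSING):
            raise ValueError("cyp2c19_group must be 1 (EM/RM), 2 (IM/PM) or 3 (missing)")


@dataclass
class ThetaVector:
    """Fixed effects of the final model (natural scale).

    ``wt_exp`` is the allometric weight exponent shared by the three
    weight relationships; it is fixed at 0.75 by convention (a switch to
    estimate it exists in the estimation module).  ``ka`` is fixed at
    1/h.
    """

    cl_rp_male: float
    cl_rp_female: float
    age_exp_r: float
    v_r: float
    cl_rm0: float
    cl_sp_emrm: float
    cl_sp_impm: float
    cl_sp_missing: float
    age_exp_s: float
    v_s: float
    cl_sm0: float
    wt_exp: float = 0.75
    ka: float = 1.0
    wt_exp_fixed: bool = True
    ka_fixed: bool = True

    def __post_init__(self) -> None:
        for name in (
            "cl_rp_male", "cl_rp_female", "v_r", "cl_rm0",
            "cl_sp_emrm", "cl_sp_impm", "cl_sp_missing", "v_s", "cl_sm0", "ka",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def covariate_factor(
    value: float, center: float, coef: float, form: str = "power"
) -> float:
    """Multiplicative covariate factor, equal to 1 at the centering value.

    ``power``: (value/center)**coef (the form retained in the final
    model); ``linear``: 1 + coef*(value - center) (the centered additive
    alternative that was evaluated during model building).
    """
    if not value > 0:
        raise ValueError("covariate value must be > 0")
    if form == "power":
        return float((value / center) ** coef)
    if form == "linear":
        return float(1.0 + coef * (value - center))
    raise ValueError(f"unknown covariate form {form!r}")


def typical_cl_rp(cov: SubjectCovariates, theta: ThetaVector) -> float:
    """Typical R-citalopram apparent metabolic clearance (L/h)."""
    if not cov.age > 0:
        raise ValueError("age must be > 0")
    base = theta.cl_rp_male if cov.sex == SEX_MALE else theta.cl_rp_female
    return base * covariate_factor(cov.age, AGE_CENTER, theta.age_exp_r)


def typical_cl_sp(cov: SubjectCovariates, theta: ThetaVector) -> float:
    """Typical S-citalopram apparent metabolic clearance (L/h)."""
    base = {
        GEN_EMRM: theta.cl_sp_emrm,
        GEN_IMPM: theta.cl_sp_impm,
        GEN_MISSING: theta.cl_sp_missing,
    }[cov.cyp2c19_group]
    return (
        base
        * covariate_factor(cov.age, AGE_CENTER, theta.age_exp_s)
        * covariate_factor(cov.weight, WT_CENTER, theta.wt_exp)
    )


def typical_cl_m(cov: SubjectCovariates, theta: ThetaVector, enantiomer: str) -> float:
    """Typical desmethylcitalopram apparent clearance (L/h), R or S."""
    if not cov.weight > 0:
        raise ValueError("weight must be > 0")
    if enantiomer == "R":
        base = theta.cl_rm0
    elif enantiomer == "S":
        base = theta.cl_sm0
    else:
        raise ValueError("enantiomer must be 'R' or 'S'")
    return base * covariate_factor(cov.weight, WT_CENTER, theta.wt_exp)


def typical_params(cov: SubjectCovariates, theta: ThetaVector) -> StructuralParams:
    """Full set of typical structural parameters for one subject."""
    return StructuralParams(
        cl_rp=typical_cl_rp(cov, theta),
        cl_sp=typical_cl_sp(cov, theta),
        cl_rm=typical_cl_m(cov, theta, "R"),
        cl_sm=typical_cl_m(cov, theta, "S"),
        v_r=theta.v_r,
        v_s=theta.v_s,
        ka=theta.ka,
    )


def sex_contrast(theta: ThetaVector) -> float:
    """Percent by which male CL_Rp exceeds female CL_Rp, relative to male."""
    if not (theta.cl_rp_male > 0 and theta.cl_rp_female > 0):
        raise ValueError("clearances must be > 0")
    return 100.0 * (theta.cl_rp_male - theta.cl_rp_female) / theta.cl_rp_male
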