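"""Synthetic sparse-sampling trial generator.

Emulates the PK substudy of a randomized citalopram-for-agitation trial
in Alzheimer's disease: 81 analyzed subjects, once-daily oral racemic
citalopram titrated over two weeks (10 mg week 1, 20 mg week 2) to the
30 mg target, and a single blood draw at each of weeks 3, 6 and 9
yielding up to four compound concentrations.  Assay censoring applies a
5 ng/mL limit of quantitation (10 ng/mL for S-desmethylcitalopram), and
independent per-compound missingness thins the records to roughly the
observation density of the real study (about 2.5 observations/subject
for the parents, fewer for the metabolites).

Demographics are drawn from the reported cohort summaries: age
truncated-normal 77.8 +/- 8.2 on [47, 90] years, weight 71.5 +/- 17.2 on
[40, 122.3] kg, 49.4% female, CYP2C19 groups EM/RM : IM/PM : missing =
56.8 : 24.7 : 18.5%.  Covariates are sampled independently of each
other, which is the main simplification relative to a real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import SubjectCovariates, ThetaVector
from .io import COLUMNS, validate_dataset
from .population import ETA_ORDER, OmegaSpec, SigmaSpec, realize_individual, residual_sd, sample_eta
from .structural import (
    CMT_DEPOT_R,
    CMT_DEPOT_S,
    CMT_OF_COMPOUND,
    COMPOUNDS,
    DoseEvent,
    RCIT,
    RDCT,
    SCIT,
    SDCT,
    once_daily_regimen,
    predict_analytic,
)

__all__ = [
    "TrialDesign",
    "DemographicsModel",
    "sample_demographics",
    "build_regimen",
    "apply_loq",
    "simulate_trial",
]


@dataclass
class TrialDesign:
    """Dosing, sampling and censoring layout of the simulated trial.

    The exact titration split (7 days at 10 mg, 7 at 20 mg) is a
    configurable convention; the study reports only a two-week titration
    to the 30 mg target.  Sampling times are drawn uniformly on
    [1, 24] h after the morning dose of the visit day.
    """

    n_subjects: int = 81
    titration: tuple[tuple[int, float], ...] = ((7, 10.0), (7, 20.0))
    maintenance_dose: float = 30.0
    visit_days: tuple[int, ...] = (21, 42, 63)
    tad_low: float = 1.0
    tad_high: float = 24.0
    missingness: dict = field(
        default_factory=lambda: {RCIT: 0.16, SCIT: 0.16, RDCT: 0.26, SDCT: 0.20}
    )
    loq: dict = field(
        default_factory=lambda: {RCIT: 5.0, SCIT: 5.0, RDCT: 5.0, SDCT: 10.0}
    )
    loq_mode: str = "drop"

    def __post_init__(self) -> None:
        titration_days = sum(d for d, _ in self.titration)
        if min(self.visit_days) < titration_days:
            raise ValueError("visits must fall after titration completes")
        if any(v < 0 for v in self.loq.values()):
            raise ValueError("LOQ values must be >= 0 (0 disables censoring)")
        if self.loq_mode not in ("drop", "flag"):
            raise ValueError("loq_mode must be 'drop' or 'flag'")


@dataclass
class DemographicsModel:
    """Marginal covariate distributions matching the cohort summaries."""

    age_mean: float = 77.8
    age_sd: float = 8.2
    age_bounds: tuple[float, float] = (47.0, 90.0)
    wt_mean: float = 71.5
    wt_sd: float = 17.2
    wt_bounds: tuple[float, float] = (40.0, 122.3)
    bmi_mean: float = 26.3
    bmi_sd: float = 5.2
    bmi_bounds: tuple[float, float] = (15.4, 41.6)
    p_female: float = 0.494
    genotype_probs: tuple[float, float, float] = (0.568, 0.247, 0.185)

    def __post_init__(self) -> None:
        if not 0 <= self.p_female <= 1:
            raise ValueError("p_female must be a probability")
        if any(p < 0 for p in self.genotype_probs) or abs(
            sum(self.genotype_probs) - 1.0
        ) > 1e-9:
            raise ValueError("genotype probabilities must be >= 0 and sum to 1")


def _truncnorm(mean, sd, bounds, n, rng):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_demographics(
    model: DemographicsModel, n: int, seed
) -> list[SubjectCovariates]:
    """Draw n independent subjects from the demographics model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        raise TypeError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    age = _truncnorm(model.age_mean, model.age_sd, model.age_bounds, n, rng)
    wt = _truncnorm(model.wt_mean, model.wt_sd, model.wt_bounds, n, rng)
    bmi = _truncnorm(model.bmi_mean, model.bmi_sd, model.bmi_bounds, n, rng)
    sex = (rng.random(n) < model.p_female).astype(int)
    gen = rng.choice([1, 2, 3], size=n, p=model.genotype_probs)
    return [
        SubjectCovariates(
            age=float(age[i]), weight=float(wt[i]), bmi=float(bmi[i]),
            sex=int(sex[i]), cyp2c19_group=int(gen[i]),
        )
        for i in range(n)
    ]


def build_regimen(design: TrialDesign, through_day: int | None = None) -> list[DoseEvent]:
    """Once-daily titrated dosing history (day 0 through ``through_day``,
    default the last visit day)."""
    if through_day is None:
        through_day = max(design.visit_days)
    daily = []
    for n_days, amount in design.titration:
        daily.extend([amount] * n_days)
    while len(daily) <= through_day:
        daily.append(design.maintenance_dose)
    return once_daily_regimen(daily[: through_day + 1])


def apply_loq(obs: float, loq: float, mode: str = "drop"):
    """Censor one concentration against its limit of quantitation.

    Returns ``None`` for a dropped record, ``(value, blq_flag)``
    otherwise.  Values exactly at the limit are retained.
    """
    if not loq > 0:
        raise ValueError("loq must be > 0")
    if obs >= loq:
        return (obs, 0)
    if mode == "drop":
        return None
    if mode == "flag":
        return (np.nan, 1)
    raise ValueError(f"unknown LOQ mode {mode!r}")


def simulate_trial(
    design: TrialDesign,
    demo: DemographicsModel,
    theta: ThetaVector,
    omega: OmegaSpec,
    sigma: SigmaSpec,
    seed,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one trial; returns (dataset, truth).

    ``dataset`` follows the event-table dialect of :mod:`citpk.io`;
    ``truth`` carries each subject's covariates, eta draws and realized
    parameters for recovery tests.
    """
    if seed is None:
        raise TypeError("an explicit seed is required (no silent global state)")
    rng = np.random.default_rng(seed)

    covs = sample_demographics(demo, design.n_subjects, rng)
    etas = sample_eta(omega, design.n_subjects, rng)
    regimen = build_regimen(design)

    rows = []
    truth_rows = []
    for i, cov in enumerate(covs):
        sid = i + 1
        indiv = realize_individual(cov, theta, etas[i])
        covcols = dict(AGE=cov.age, WT=cov.weight, BMI=cov.bmi,
                       SEX=cov.sex, GEN=cov.cyp2c19_group)

        for d in regimen:
            for cmt in (CMT_DEPOT_R, CMT_DEPOT_S):
                rows.append(dict(ID=sid, TIME=d.time, EVID=1,
                                 AMT=d.racemic_amount / 2.0, CMT=cmt,
                                 DV=np.nan, MDV=1, BLQ=0, **covcols))

        obs_times = np.array(
            [24.0 * day + rng.uniform(design.tad_low, design.tad_high)
             for day in design.visit_days]
        )
        profile = predict_analytic(regimen, indiv, obs_times)
        for v, t in enumerate(obs_times):
            for compound in COMPOUNDS:
                missed = rng.random() < design.missingness.get(compound, 0.0)
                pred = profile.conc[compound][v]
                noisy = pred + rng.normal(0.0, residual_sd(pred, compound, sigma))
                if missed:
                    continue
                dv = max(noisy, 0.0)  # physical floor before censoring
                loq = design.loq[compound]
                if loq > 0:
                    kept = apply_loq(dv, loq, design.loq_mode)
                    if kept is None:
                        continue
                    value, blq = kept
                else:
                    value, blq = dv, 0
                rows.append(dict(ID=sid, TIME=t, EVID=0, AMT=np.nan,
                                 CMT=CMT_OF_COMPOUND[compound],
                                 DV=value, MDV=blq, BLQ=blq, **covcols))

        truth = dict(ID=sid, **covcols)
        truth.update({f"eta_{k}": etas[i, j] for j, k in enumerate(ETA_ORDER)})
        truth.update(
            cl_rp=indiv.cl_rp, v_r=indiv.v_r, cl_rm=indiv.cl_rm,
            cl_sp=indiv.cl_sp, v_s=indiv.v_s, cl_sm=indiv.cl_sm,
        )
        truth_rows.append(truth)

    df = pd.DataFrame(rows)[COLUMNS]
    df = df.sort_values(
        ["ID", "TIME", "EVID"], ascending=[True, True, False], kind="stable"
    ).reset_index(drop=True)
    return validate_dataset(df), pd.DataFrame(truth_rows)
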