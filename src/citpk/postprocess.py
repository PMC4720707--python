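"""Diagnostics and derived quantities from a fitted population model.

Covers conditional weighted residuals (CWRES) under the FOCE
linearization, empirical-Bayes-based subgroup summaries of realized
clearances, steady-state exposure (AUC) summaries, and the two-sample
Mann-Whitney U contrast used to compare enantiomers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import ThetaVector
from .estimate import (
    _final_subject_problem,
    estimate_eta,
)
from .io import split_by_subject
from .population import OmegaSpec, SigmaSpec

__all__ = [
    "cwres",
    "individual_parameters",
    "subgroup_summary",
    "exposure_summary",
    "mann_whitney",
]


def _inv_sqrt(mat: np.ndarray, ridge: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Symmetric inverse square root; returns (matrix, was_regularized)."""
    vals, vecs = np.linalg.eigh(mat)
    regularized = bool(vals.min() <= ridge * max(vals.max(), 1.0))
    vals = np.maximum(vals, ridge * max(vals.max(), 1.0))
    return (vecs / np.sqrt(vals)) @ vecs.T, regularized


def cwres(
    ds,
    theta: ThetaVector,
    omega: OmegaSpec,
    sigma: SigmaSpec,
) -> pd.DataFrame:
    """Conditional weighted residuals of the final model on a dataset.

    FOCE linearization about each subject's posterior-mode eta: with
    ``J`` the sensitivity of the prediction to eta at eta_hat, the
    marginal mean is approximated by ``f(eta_hat) - J eta_hat`` and the
    marginal covariance by ``J Omega J' + diag(sd^2)`` (residual SD at
    the conditional prediction); residuals are whitened by the symmetric
    inverse square root of that covariance.  A singular covariance is
    ridge-regularized and flagged per subject.
    """
    records = split_by_subject(ds) if isinstance(ds, pd.DataFrame) else list(ds)
    om = omega.matrix()
    zero_omega = not om.any()
    rows = []
    for rec in records:
        y, predict, sigma_fn, compounds = _final_subject_problem(rec, theta, sigma)
        if y.size == 0:
            continue
        if zero_omega:
            eta_hat = np.zeros(6)
            pred = predict(eta_hat)
            sd, _ = sigma_fn(pred)
            mean = pred
            cov = np.diag(sd**2)
            jac = np.zeros((y.size, 6))
        else:
            res = estimate_eta(y, predict, sigma_fn, om)
            eta_hat, pred, jac, sd = res.eta, res.pred, res.jac, res.sd
            mean = pred - jac @ eta_hat
            cov = jac @ om @ jac.T + np.diag(sd**2)
        whitener, regularized = _inv_sqrt(cov)
        w = whitener @ (y - mean)
        pop_pred = predict(np.zeros(6))
        for j in range(y.size):
            rows.append(
                {
                    "ID": rec.subject_id,
                    "compound": compounds[j],
                    "DV": y[j],
                    "PRED": pop_pred[j],
                    "IPRED": pred[j],
                    "RES": y[j] - pred[j],
                    "CWRES": w[j],
                    "regularized": regularized,
                }
            )
    out = pd.DataFrame(rows)
    if not np.all(np.isfinite(out["CWRES"])):
        raise FloatingPointError("non-finite CWRES")
    return out


def individual_parameters(
    ds, theta: ThetaVector, omega: OmegaSpec, sigma: SigmaSpec
) -> pd.DataFrame:
    """Empirical-Bayes realized parameters per subject: typical value
    from the covariates times exp(eta_hat), plus derived half-lives."""
    from .covariates import typical_params
    from .structural import half_life

    records = split_by_subject(ds) if isinstance(ds, pd.DataFrame) else list(ds)
    om = omega.matrix()
    rows = []
    for rec in records:
        y, predict, sigma_fn, _ = _final_subject_problem(rec, theta, sigma)
        if y.size:
            eta = estimate_eta(y, predict, sigma_fn, om).eta
        else:
            eta = np.zeros(6)
        typ = typical_params(rec.covariates, theta)
        cl_rp = typ.cl_rp * np.exp(eta[0])
        v_r = typ.v_r * np.exp(eta[1])
        cl_rm = typ.cl_rm * np.exp(eta[2])
        cl_sp = typ.cl_sp * np.exp(eta[3])
        v_s = typ.v_s * np.exp(eta[4])
        cl_sm = typ.cl_sm * np.exp(eta[5])
        cov = rec.covariates
        rows.append(
            {
                "ID": rec.subject_id,
                "age": cov.age, "weight": cov.weight, "bmi": cov.bmi,
                "sex": cov.sex, "genotype": cov.cyp2c19_group,
                "cl_rp": cl_rp, "v_r": v_r, "cl_rm": cl_rm,
                "cl_sp": cl_sp, "v_s": v_s, "cl_sm": cl_sm,
                "thalf_r": half_life(cl_rp, v_r),
                "thalf_s": half_life(cl_sp, v_s),
            }
        )
    return pd.DataFrame(rows)


_GROUPINGS = ("sex", "age_band", "weight_band", "genotype")


def _group_labels(table: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "sex":
        return table["sex"].map({0: "male", 1: "female"})
    if grouping == "age_band":
        return pd.cut(
            table["age"], bins=[0, 70, 80, np.inf], right=False,
            labels=["<70", "70-79", "80-90"],
        ).astype(str)
    if grouping == "weight_band":
        return np.where(table["weight"] < 70, "<70kg", ">=70kg")
    if grouping == "genotype":
        return table["genotype"].map({1: "EM/RM", 2: "IM/PM", 3: "missing"})
    raise ValueError(f"grouping must be one of {_GROUPINGS}")


@dataclass
class SubgroupSummary:
    groups: pd.DataFrame     # n, mean, sd per group
    contrasts: pd.DataFrame  # pairwise percent differences


def subgroup_summary(
    table: pd.DataFrame, value: str, grouping: str
) -> SubgroupSummary:
    """Group means +/- SD of a realized-parameter column, with pairwise
    percent contrasts computed as (faster - slower)/slower * 100 --
    i.e. how much faster the larger-mean group is relative to the
    smaller.  Empty groups are absent from the output, not zero."""
    labels = pd.Series(_group_labels(table, grouping), index=table.index)
    groups = (
        table.groupby(labels, observed=True)[value]
        .agg(n="size", mean="mean", sd="std")
        .dropna(subset=["mean"])
    )
    names = list(groups.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups.loc[names[i], "mean"], groups.loc[names[j], "mean"]
            fast, slow = (names[i], names[j]) if a >= b else (names[j], names[i])
            hi, lo = max(a, b), min(a, b)
            rows.append(
                {
                    "faster": fast,
                    "slower": slow,
                    "percent_faster": 100.0 * (hi - lo) / lo,
                }
            )
    return SubgroupSummary(groups=groups, contrasts=pd.DataFrame(rows))


def exposure_summary(
    indiv: pd.DataFrame, daily_racemic_dose: float = 30.0
) -> pd.DataFrame:
    """Per-enantiomer steady-state daily exposure, AUC = dose/CL over 24 h.

    Each enantiomer receives half the racemic daily dose.  Returns group
    mean +/- SD (mg*h/L) for the parents and metabolites plus the R vs S
    parent Mann-Whitney contrast.
    """
    half_dose = daily_racemic_dose / 2.0
    auc = {
        "R-citalopram": half_dose / indiv["cl_rp"],
        "S-citalopram": half_dose / indiv["cl_sp"],
        "R-desmethylcitalopram": half_dose / indiv["cl_rm"],
        "S-desmethylcitalopram": half_dose / indiv["cl_sm"],
    }
    _, p_parent = mann_whitney(auc["R-citalopram"].to_numpy(),
                               auc["S-citalopram"].to_numpy())
    rows = []
    for name, series in auc.items():
        rows.append(
            {
                "compound": name,
                "mean_auc_mg_h_L": series.mean(),
                "sd_auc_mg_h_L": series.std(),
                "p_R_vs_S_parent": p_parent if "citalopram" == name.split("-")[1] else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.loc[out["compound"].str.endswith("desmethylcitalopram"), "p_R_vs_S_parent"] = np.nan
    return out


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (statistic of the first sample) and two-sided p.

    Exact enumeration when both samples have at most 8 values and no
    ties span the groups; otherwise the tie-corrected normal
    approximation.  Identical pooled values give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
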