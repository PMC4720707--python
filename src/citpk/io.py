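"""Rectangular event-dataset dialect shared by the simulator and estimator.

One CSV row per event, NONMEM-style: dose rows (EVID=1, AMT in mg into a
depot compartment) and observation rows (EVID=0, DV in ng/mL).
Compartment codes: 1 R-depot, 2 S-depot, 3 R-citalopram,
4 S-citalopram, 5 R-desmethylcitalopram, 6 S-desmethylcitalopram.
Covariates (AGE, WT, BMI, SEX, GEN) are repeated on every row and must
be constant within a subject.  Rows are sorted by (ID, TIME, EVID
descending) so doses precede observations at a shared time.  BLQ-flagged
rows carry MDV=1 and a blank DV and never enter likelihood computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import SubjectCovariates
from .structural import CMT_DEPOT_R, CMT_DEPOT_S, COMPOUND_OF_CMT, RCIT, RDCT

__all__ = ["COLUMNS", "DatasetError", "read_dataset", "write_dataset",
           "validate_dataset", "SubjectRecord", "split_by_subject"]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "CMT", "DV", "MDV", "BLQ",
           "AGE", "WT", "BMI", "SEX", "GEN"]

_DEPOTS = (CMT_DEPOT_R, CMT_DEPOT_S)


class DatasetError(ValueError):
    """Raised when a dataset violates the dialect's invariants."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    df = df[COLUMNS].copy()

    for i, row in enumerate(df.itertuples(index=False)):
        ctx = f"row {i} (ID={row.ID}, TIME={row.TIME})"
        if row.EVID not in (0, 1):
            raise DatasetError(f"{ctx}: EVID must be 0 or 1")
        if row.EVID == 1:
            if row.CMT not in _DEPOTS:
                raise DatasetError(f"{ctx}: dose rows must target a depot (CMT 1 or 2)")
            if not row.AMT > 0:
                raise DatasetError(f"{ctx}: dose row requires AMT > 0")
            if not (pd.isna(row.DV)):
                raise DatasetError(f"{ctx}: DV must be blank on a dose row")
        else:
            if row.CMT not in COMPOUND_OF_CMT:
                raise DatasetError(f"{ctx}: observation CMT must be 3-6")
            if row.MDV == 0:
                if pd.isna(row.DV):
                    raise DatasetError(f"{ctx}: MDV=0 observation requires DV")
                if row.DV < 0:
                    raise DatasetError(f"{ctx}: negative DV")
            elif not pd.isna(row.DV):
                raise DatasetError(f"{ctx}: DV must be blank when MDV=1")

    # sorted by (ID, TIME, EVID desc)
    key = df[["ID", "TIME"]].assign(NEGEVID=-df["EVID"])
    if not key.equals(key.sort_values(["ID", "TIME", "NEGEVID"], kind="stable")):
        raise DatasetError("rows must be sorted by (ID, TIME, EVID descending)")

    for col in ("AGE", "WT", "BMI", "SEX", "GEN"):
        if (df.groupby("ID")[col].nunique() > 1).any():
            raise DatasetError(f"covariate {col} varies within a subject")
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a validated dataset as CSV ('.' decimal, blank missing DV)."""
    validate_dataset(df).to_csv(path, index=False, na_rep="")


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV."""
    df = pd.read_csv(path)
    return validate_dataset(df)


@dataclass
class SubjectRecord:
    """One subject's dosing history and observations, dialect-decoded."""

    subject_id: int
    covariates: SubjectCovariates
    dose_times: np.ndarray      # per depot row, hours
    dose_amounts: np.ndarray    # enantiomer mg entering the depot
    dose_cmt: np.ndarray        # 1 (R depot) or 2 (S depot)
    obs_times: np.ndarray
    obs_compound: np.ndarray    # compound labels, e.g. "RCIT"
    dv: np.ndarray              # ng/mL, NaN on BLQ-flagged rows
    blq: np.ndarray             # bool

    def enantiomer_view(self, enantiomer: str):
        """(dose_times, dose_amounts, obs_times, is_metabolite, dv) for
        one enantiomer, restricted to quantifiable (non-BLQ) observations."""
        if enantiomer == "R":
            depot, parent, metab = CMT_DEPOT_R, RCIT, RDCT
        elif enantiomer == "S":
            depot, parent, metab = CMT_DEPOT_S, "SCIT", "SDCT"
        else:
            raise ValueError("enantiomer must be 'R' or 'S'")
        dmask = self.dose_cmt == depot
        omask = np.isin(self.obs_compound, [parent, metab]) & ~self.blq
        return (
            self.dose_times[dmask],
            self.dose_amounts[dmask],
            self.obs_times[omask],
            self.obs_compound[omask] == metab,
            self.dv[omask],
        )


def split_by_subject(df: pd.DataFrame) -> list[SubjectRecord]:
    """Partition a validated dataset into per-subject records, preserving
    order.  Subjects whose observations were all censored away are kept
    (empty observation arrays)."""
    records = []
    for sid, grp in df.groupby("ID", sort=False):
        first = grp.iloc[0]
        cov = SubjectCovariates(
            age=float(first["AGE"]),
            weight=float(first["WT"]),
            bmi=float(first["BMI"]),
            sex=int(first["SEX"]),
            cyp2c19_group=int(first["GEN"]),
        )
        doses = grp[grp["EVID"] == 1]
        obs = grp[grp["EVID"] == 0]
        records.append(
            SubjectRecord(
                subject_id=int(sid),
                covariates=cov,
                dose_times=doses["TIME"].to_numpy(float),
                dose_amounts=doses["AMT"].to_numpy(float),
                dose_cmt=doses["CMT"].to_numpy(int),
                obs_times=obs["TIME"].to_numpy(float),
                obs_compound=np.array(
                    [COMPOUND_OF_CMT[int(c)] for c in obs["CMT"]], dtype=object
                ),
                dv=obs["DV"].to_numpy(float),
                blq=obs["BLQ"].to_numpy(int).astype(bool),
            )
        )
    return records
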