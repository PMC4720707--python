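"""One-compartment parent-metabolite kinetics for racemic citalopram.

Racemic citalopram is a 50/50 mixture of the R- and S-enantiomer; each
enantiomer is demethylated to its desmethyl metabolite, giving four
observed compounds (R-citalopram, S-citalopram, R- and
S-desmethylcitalopram).  The disposition model per enantiomer is a
first-order absorption depot feeding a one-compartment parent with
complete conversion to a one-compartment metabolite with linear
elimination.  Parent and metabolite of an enantiomer share the apparent
volume of distribution, and the absorption rate constant is common to
both enantiomers.  All clearances and volumes are apparent quantities
(CL/F, V/F): only oral racemate data exist, so bioavailability is not
separately identifiable and is folded into the parameters.

Unit conventions: doses in mg, volumes in L, clearances in L/h, times in
hours since first dose.  Internal concentrations are mg/L; exported
concentrations are ng/mL (x 1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RCIT",
    "SCIT",
    "RDCT",
    "SDCT",
    "COMPOUNDS",
    "CMT_OF_COMPOUND",
    "COMPOUND_OF_CMT",
    "StructuralParams",
    "DoseEvent",
    "ConcentrationProfile",
    "ode_rhs",
    "predict_analytic",
    "predict_ode",
    "concentration_mgl",
    "exp_dd2",
    "exp_dd3",
    "half_life",
    "auc_at_steady_state",
    "once_daily_regimen",
]

RCIT = "RCIT"
SCIT = "SCIT"
RDCT = "RDCT"
SDCT = "SDCT"
COMPOUNDS = (RCIT, SCIT, RDCT, SDCT)

#: dataset compartment codes: 1/2 are the R and S depots, 3-6 the observed compounds
CMT_DEPOT_R = 1
CMT_DEPOT_S = 2
CMT_OF_COMPOUND = {RCIT: 3, SCIT: 4, RDCT: 5, SDCT: 6}
COMPOUND_OF_CMT = {v: k for k, v in CMT_OF_COMPOUND.items()}

MGL_TO_NGML = 1000.0

# rate constants closer than this (relative to the largest) take the
# confluent (L'Hopital) branch instead of dividing by a near-zero gap
_CONFLUENT_RTOL = 1e-8
_CONFLUENT_RTOL_DD3 = 1e-5


@dataclass
class StructuralParams:
    """Kinetic constants for one individual (apparent CL/F and V/F).

    ``ka`` is shared by both enantiomers and fixed at 1/h by default
    (sparse sampling at 1-24 h after dose does not inform absorption).
    """

    cl_rp: float
    cl_sp: float
    cl_rm: float
    cl_sm: float
    v_r: float
    v_s: float
    ka: float = 1.0
    ka_fixed: bool = True

    def __post_init__(self) -> None:
        for name in ("cl_rp", "cl_sp", "cl_rm", "cl_sm", "v_r", "v_s", "ka"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and > 0, got {val!r}")


@dataclass(frozen=True)
class DoseEvent:
    """One oral administration of racemic citalopram.

    Each enantiomer depot receives ``racemic_amount / 2`` (50/50 racemate).
    """

    time: float
    racemic_amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0 (hours since first dose)")
        if not self.racemic_amount > 0:
            raise ValueError("dose amount must be > 0 mg")


@dataclass
class ConcentrationProfile:
    """Predicted concentrations (ng/mL) for the four compounds."""

    times: np.ndarray
    conc: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tidy(self, subject_id: int = 1) -> pd.DataFrame:
        rows = []
        for compound in COMPOUNDS:
            rows.append(
                pd.DataFrame(
                    {
                        "id": subject_id,
                        "time_h": self.times,
                        "compound": compound,
                        "conc_ng_ml": self.conc[compound],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def once_daily_regimen(
    daily_doses: list[float] | np.ndarray, start_hour: float = 0.0
) -> list[DoseEvent]:
    """Build a once-daily regimen, one dose per entry of ``daily_doses`` (mg)."""
    return [
        DoseEvent(time=start_hour + 24.0 * day, racemic_amount=float(amt))
        for day, amt in enumerate(daily_doses)
    ]


# ---------------------------------------------------------------------------
# confluent-safe exponential divided differences
#
# A linear cascade depot -> parent -> metabolite has solutions that are
# divided differences of exp(-k t) over the participating rate constants;
# writing them this way gives one code path whose degenerate (equal-rate)
# limits are explicit instead of dividing by ~0.
# ---------------------------------------------------------------------------


def exp_dd2(k1: float, k2: float, t: np.ndarray) -> np.ndarray:
    """(exp(-k2 t) - exp(-k1 t)) / (k1 - k2), confluent limit t exp(-k t).

    Accepts complex rate constants so callers can differentiate
    predictions by the complex-step method.
    """
    t = np.asarray(t)
    if abs(k1 - k2) < _CONFLUENT_RTOL * max(abs(k1), abs(k2)):
        k = 0.5 * (k1 + k2)
        return t * np.exp(-k * t)
    return (np.exp(-k2 * t) - np.exp(-k1 * t)) / (k1 - k2)


def exp_dd3(k1: float, k2: float, k3: float, t: np.ndarray) -> np.ndarray:
    """sum_i exp(-k_i t) / prod_{j != i} (k_j - k_i), confluent-safe.

    This is the three-exponential kernel of the depot -> parent ->
    metabolite cascade (second divided difference of exp(-k t)).  The
    confluent switch is wider than the two-rate kernel's because the
    second divided difference loses two orders of cancellation: below a
    relative gap of ~1e-5 the distinct-rate formula is pure round-off
    while the confluent limit is accurate to O(gap).
    """
    t = np.asarray(t)
    tol = _CONFLUENT_RTOL_DD3 * max(abs(k1), abs(k2), abs(k3))
    close12 = abs(k1 - k2) < tol
    close13 = abs(k1 - k3) < tol
    close23 = abs(k2 - k3) < tol
    n_close = close12 + close13 + close23
    if n_close >= 2:
        k = (k1 + k2 + k3) / 3.0
        return 0.5 * t * t * np.exp(-k * t)
    if close12:
        a, c = 0.5 * (k1 + k2), k3
    elif close13:
        a, c = 0.5 * (k1 + k3), k2
    elif close23:
        a, c = 0.5 * (k2 + k3), k1
    else:
        return (
            np.exp(-k1 * t) / ((k2 - k1) * (k3 - k1))
            + np.exp(-k2 * t) / ((k1 - k2) * (k3 - k2))
            + np.exp(-k3 * t) / ((k1 - k3) * (k2 - k3))
        )
    # two rates coincide at a, third is c
    return (np.exp(-a * t) * (t * (c - a) - 1.0) + np.exp(-c * t)) / (c - a) ** 2


def concentration_mgl(
    dose_times: np.ndarray,
    dose_amounts: np.ndarray,
    times: np.ndarray,
    ka: float,
    cl_p: float,
    v: float,
    cl_m: float | None = None,
    metabolite: bool = False,
    cl_excreted: float = 0.0,
) -> np.ndarray:
    """Parent or metabolite concentration (mg/L) for one enantiomer.

    ``dose_amounts`` are the enantiomer amounts (mg) entering this
    enantiomer's depot (half the racemic dose).  ``cl_excreted`` is an
    optional direct parent elimination clearance (the partial-conversion
    model variant); under complete conversion it is 0 and all parent
    elimination forms the metabolite.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    out_dtype = np.result_type(float, cl_p, v, cl_m if cl_m is not None else 0.0)
    if dose_times.size == 0 or times.size == 0:
        return np.zeros(times.shape, dtype=out_dtype)

    kp = (cl_p + cl_excreted) / v
    dt = times[:, None] - dose_times[None, :]
    mask = dt > 0
    dt = np.where(mask, dt, 0.0)
    if metabolite:
        if cl_m is None:
            raise ValueError("cl_m is required for a metabolite prediction")
        km = cl_m / v
        unit = (ka * (cl_p / v) / v) * exp_dd3(ka, kp, km, dt)
    else:
        unit = (ka / v) * exp_dd2(ka, kp, dt)
    return np.where(mask, unit, 0.0) @ dose_amounts


def predict_analytic(
    regimen: list[DoseEvent],
    params: StructuralParams,
    times: np.ndarray,
) -> ConcentrationProfile:
    """Closed-form concentration-time profiles (ng/mL) under superposition."""
    times = np.asarray(times, dtype=float)
    dose_times = np.array([d.time for d in regimen], dtype=float)
    half = np.array([d.racemic_amount for d in regimen], dtype=float) / 2.0

    conc: dict[str, np.ndarray] = {}
    for enant, (parent, metab) in {"R": (RCIT, RDCT), "S": (SCIT, SDCT)}.items():
        cl_p = params.cl_rp if enant == "R" else params.cl_sp
        cl_m = params.cl_rm if enant == "R" else params.cl_sm
        v = params.v_r if enant == "R" else params.v_s
        conc[parent] = MGL_TO_NGML * concentration_mgl(
            dose_times, half, times, params.ka, cl_p, v
        )
        conc[metab] = MGL_TO_NGML * concentration_mgl(
            dose_times, half, times, params.ka, cl_p, v, cl_m=cl_m, metabolite=True
        )
    return ConcentrationProfile(times=times, conc=conc)


def ode_rhs(state: np.ndarray, params: StructuralParams) -> np.ndarray:
    """Right-hand side of the six-state system.

    State: [R depot (mg), S depot (mg), C1 R-cit, C2 S-cit, C3 R-DCT,
    C4 S-DCT] with C* in mg/L.  Complete conversion: all parent
    elimination is formation of the corresponding metabolite.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (6,):
        raise ValueError("state must have 6 entries (2 depots + 4 compounds)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to ode_rhs")
    a_r, a_s, c1, c2, c3, c4 = state
    ka, vr, vs = params.ka, params.v_r, params.v_s
    return np.array(
        [
            -ka * a_r,
            -ka * a_s,
            ka * a_r / vr - params.cl_rp / vr * c1,
            ka * a_s / vs - params.cl_sp / vs * c2,
            params.cl_rp / vr * c1 - params.cl_rm / vr * c3,
            params.cl_sp / vs * c2 - params.cl_sm / vs * c4,
        ]
    )


def predict_ode(
    regimen: list[DoseEvent],
    params: StructuralParams,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> ConcentrationProfile:
    """Reference prediction by adaptive ODE integration (oracle for the
    closed form).  Doses are bolus additions to the depots; integration is
    piecewise between dose events."""
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    if times.size == 0 or not regimen:
        zero = np.zeros(times.shape)
        return ConcentrationProfile(
            times=times, conc={c: zero.copy() for c in COMPOUNDS}
        )

    events = sorted(regimen, key=lambda d: d.time)
    t_end = float(max(times.max(), events[-1].time))
    boundaries = sorted({d.time for d in events} | {t_end})
    dose_at = {}
    for d in events:
        dose_at[d.time] = dose_at.get(d.time, 0.0) + d.racemic_amount

    def rhs(_t, y):
        return ode_rhs(y, params)

    state = np.zeros(6)
    out = np.zeros((6, times.size))
    t_cur = 0.0
    for bound in boundaries:
        if bound > t_cur:
            sol = solve_ivp(
                rhs, (t_cur, bound), state,
                dense_output=True, rtol=rtol, atol=atol, method="LSODA",
            )
            if not sol.success:
                raise FloatingPointError(f"ODE integration failed: {sol.message}")
            sel = (times > t_cur) & (times <= bound)
            if sel.any():
                out[:, sel] = sol.sol(times[sel])
            state = sol.y[:, -1]
            t_cur = bound
        if bound in dose_at:
            state = state.copy()
            state[0] += dose_at[bound] / 2.0
            state[1] += dose_at[bound] / 2.0

    conc = {
        RCIT: out[2] * MGL_TO_NGML,
        SCIT: out[3] * MGL_TO_NGML,
        RDCT: out[4] * MGL_TO_NGML,
        SDCT: out[5] * MGL_TO_NGML,
    }
    return ConcentrationProfile(times=times, conc=conc)


def half_life(cl: float, v: float) -> float:
    """Elimination half-life ln(2) * V / CL (hours)."""
    if not (cl > 0 and v > 0):
        raise ValueError("cl and v must be > 0")
    return math.log(2.0) * v / cl


def auc_at_steady_state(dose_per_interval: float, cl: float) -> float:
    """Steady-state AUC over one dosing interval, dose/CL (mg*h/L).

    For apparent-clearance parameterization with complete conversion the
    metabolite AUC over an interval is dose/CL_m.
    """
    if not (dose_per_interval > 0 and cl > 0):
        raise ValueError("dose and cl must be > 0")
    return dose_per_interval / cl
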