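"""Random-effect (BSV) and residual-error layers of the population model.

Between-subject variability is log-normal: each structural parameter for
subject j is ``typical * exp(eta)`` with eta ~ N(0, omega^2).  Six eta
coordinates are modelled, in the fixed order

    (CL_Rp, V_R, CL_Rm, CL_Sp, V_S, CL_Sm).

The R-enantiomer etas are mutually independent (diagonal block); on the
S side CL_Sp and V_S share a 2x2 covariance block and CL_Sm is
independent.  ka carries no BSV.  Variability magnitudes are reported in
percent as 100*sqrt(variance) (100*sqrt(covariance) for the off-diagonal
term), the common mixed-effects reporting convention.

Residual error is compound-specific: additive (ng/mL) for R-citalopram,
proportional for R-desmethylcitalopram, and a single shared proportional
term for S-citalopram and S-desmethylcitalopram.  Under estimation with
interaction the residual SD is evaluated at the individual (conditional)
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariates import SubjectCovariates, ThetaVector, typical_params
from .structural import RCIT, RDCT, SCIT, SDCT, StructuralParams

__all__ = [
    "ETA_ORDER",
    "OmegaSpec",
    "SigmaSpec",
    "sample_eta",
    "realize_individual",
    "residual_sd",
]

ETA_ORDER = ("cl_rp", "v_r", "cl_rm", "cl_sp", "v_s", "cl_sm")


def _pct_to_var(pct: float) -> float:
    return (pct / 100.0) ** 2


def _var_to_pct(var: float) -> float:
    return 100.0 * np.sqrt(var)


@dataclass
class OmegaSpec:
    """BSV covariance: R diagonal block + S (CLp, V) block + S CLm.

    Fields are variances (covariance for ``cov_cl_v_s``) on the natural
    eta scale.
    """

    var_cl_rp: float
    var_v_r: float
    var_cl_rm: float
    var_cl_sp: float
    var_v_s: float
    cov_cl_v_s: float
    var_cl_sm: float

    def __post_init__(self) -> None:
        for name in ("var_cl_rp", "var_v_r", "var_cl_rm", "var_cl_sp",
                     "var_v_s", "cov_cl_v_s", "var_cl_sm"):
            setattr(self, name, float(getattr(self, name)))
        for name in ("var_cl_rp", "var_v_r", "var_cl_rm", "var_cl_sp",
                     "var_v_s", "var_cl_sm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        s = self.s_block()
        if np.linalg.eigvalsh(s).min() < -1e-12:
            raise ValueError("S-enantiomer (CLp, V) block is not positive semi-definite")

    @classmethod
    def from_percent(
        cls,
        cl_rp: float,
        v_r: float,
        cl_rm: float,
        cl_sp: float,
        v_s: float,
        cov_cl_v_s: float,
        cl_sm: float,
    ) -> "OmegaSpec":
        """Build from percent reporting, 100*sqrt(variance or covariance)."""
        sign = np.sign(cov_cl_v_s) or 1.0
        return cls(
            var_cl_rp=_pct_to_var(cl_rp),
            var_v_r=_pct_to_var(v_r),
            var_cl_rm=_pct_to_var(cl_rm),
            var_cl_sp=_pct_to_var(cl_sp),
            var_v_s=_pct_to_var(v_s),
            cov_cl_v_s=sign * _pct_to_var(abs(cov_cl_v_s)),
            var_cl_sm=_pct_to_var(cl_sm),
        )

    def to_percent(self) -> dict[str, float]:
        sign = np.sign(self.cov_cl_v_s) or 1.0
        return {
            "cl_rp": _var_to_pct(self.var_cl_rp),
            "v_r": _var_to_pct(self.var_v_r),
            "cl_rm": _var_to_pct(self.var_cl_rm),
            "cl_sp": _var_to_pct(self.var_cl_sp),
            "v_s": _var_to_pct(self.var_v_s),
            "cov_cl_v_s": sign * _var_to_pct(abs(self.cov_cl_v_s)),
            "cl_sm": _var_to_pct(self.var_cl_sm),
        }

    def s_block(self) -> np.ndarray:
        """2x2 covariance of the S-enantiomer (CLp, V) etas."""
        return np.array(
            [[self.var_cl_sp, self.cov_cl_v_s], [self.cov_cl_v_s, self.var_v_s]]
        )

    def matrix(self) -> np.ndarray:
        """Full 6x6 covariance in ``ETA_ORDER``."""
        m = np.zeros((6, 6))
        m[0, 0] = self.var_cl_rp
        m[1, 1] = self.var_v_r
        m[2, 2] = self.var_cl_rm
        m[3:5, 3:5] = self.s_block()
        m[5, 5] = self.var_cl_sm
        return m


@dataclass
class SigmaSpec:
    """Residual-error magnitudes.

    ``rcit_additive_sd`` in ng/mL; the proportional terms are fractions
    of the prediction (0.2154 <-> 21.54%).
    """

    rcit_additive_sd: float
    rdct_prop_sd: float
    s_prop_sd: float

    def __post_init__(self) -> None:
        for name in ("rcit_additive_sd", "rdct_prop_sd", "s_prop_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def sample_eta(omega: OmegaSpec, n: int, seed) -> np.ndarray:
    """Draw n eta vectors (n, 6) from N(0, Omega).

    ``seed`` is mandatory (int or numpy Generator) -- no silent global
    randomness.
    """
    if seed is None:
        raise TypeError("an explicit seed (int or numpy Generator) is required")
    rng = np.random.default_rng(seed)
    cov = omega.matrix()
    if np.linalg.eigvalsh(cov).min() < -1e-12:
        raise ValueError("omega is not positive semi-definite")
    return rng.multivariate_normal(np.zeros(6), cov, size=n, method="svd")


def realize_individual(
    cov: SubjectCovariates, theta: ThetaVector, eta: np.ndarray
) -> StructuralParams:
    """Individual parameters: typical value times exp(eta), per ETA_ORDER."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (6,):
        raise ValueError("eta must have 6 coordinates (R: CLp, V, CLm; S: CLp, V, CLm)")
    typ = typical_params(cov, theta)
    return StructuralParams(
        cl_rp=typ.cl_rp * np.exp(eta[0]),
        v_r=typ.v_r * np.exp(eta[1]),
        cl_rm=typ.cl_rm * np.exp(eta[2]),
        cl_sp=typ.cl_sp * np.exp(eta[3]),
        v_s=typ.v_s * np.exp(eta[4]),
        cl_sm=typ.cl_sm * np.exp(eta[5]),
        ka=typ.ka,
    )


def residual_sd(pred: float | np.ndarray, compound: str, sigma: SigmaSpec):
    """Residual SD (ng/mL) at prediction ``pred`` for one compound."""
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be >= 0")
    if compound == RCIT:
        out = np.full(pred.shape, sigma.rcit_additive_sd)
    elif compound == RDCT:
        out = pred * sigma.rdct_prop_sd
    elif compound in (SCIT, SDCT):
        out = pred * sigma.s_prop_sd
    else:
        raise ValueError(f"unknown compound {compound!r}")
    return out if out.shape else float(out)
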