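"""YAML/JSON serialization of model parameters and trial configuration.

The on-disk schema groups parameters on the natural scale:

    theta: {cl_rp_male: 13.0, ..., wt_exp: 0.75, ka: 1.0,
            wt_exp_fixed: true, ka_fixed: true}
    omega: {r: {cl_rp: ..., v_r: ..., cl_rm: ...},
            s: {cl_sp: ..., v_s: ..., cov_clp_v: ..., cl_sm: ...}}
    sigma: {rcit_additive_sd: ..., rdct_prop_sd: ..., s_prop_sd: ...}

Omega entries are variances (covariance for ``cov_clp_v``).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .covariates import ThetaVector
from .population import OmegaSpec, SigmaSpec

__all__ = ["params_to_dict", "params_from_dict", "save_params", "load_params"]


def params_to_dict(theta: ThetaVector, omega: OmegaSpec, sigma: SigmaSpec) -> dict:
    return {
        "theta": asdict(theta),
        "omega": {
            "r": {"cl_rp": omega.var_cl_rp, "v_r": omega.var_v_r,
                  "cl_rm": omega.var_cl_rm},
            "s": {"cl_sp": omega.var_cl_sp, "v_s": omega.var_v_s,
                  "cov_clp_v": omega.cov_cl_v_s, "cl_sm": omega.var_cl_sm},
        },
        "sigma": asdict(sigma),
    }


def params_from_dict(d: dict) -> tuple[ThetaVector, OmegaSpec, SigmaSpec]:
    theta = ThetaVector(**d["theta"])
    om = d["omega"]
    omega = OmegaSpec(
        var_cl_rp=om["r"]["cl_rp"], var_v_r=om["r"]["v_r"],
        var_cl_rm=om["r"]["cl_rm"],
        var_cl_sp=om["s"]["cl_sp"], var_v_s=om["s"]["v_s"],
        cov_cl_v_s=om["s"]["cov_clp_v"], var_cl_sm=om["s"]["cl_sm"],
    )
    sigma = SigmaSpec(**d["sigma"])
    return theta, omega, sigma


def save_params(path, theta: ThetaVector, omega: OmegaSpec, sigma: SigmaSpec) -> None:
    path = Path(path)
    payload = params_to_dict(theta, omega, sigma)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_params(path) -> tuple[ThetaVector, OmegaSpec, SigmaSpec]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return params_from_dict(payload)
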