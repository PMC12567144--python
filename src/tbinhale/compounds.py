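"""Compound parameter blocks for the three anti-tuberculosis APIs.

Each compound carries the full PBPK/dosing parameterization: the clinical
trial dose used for model validation, the common therapeutic oral dose used
for dose translation, molecular weights of the free and dosed (salt) forms,
blood-to-plasma ratio, unbound fraction, steady-state volume of distribution,
effective intestinal permeability, systemic and renal plasma clearances, and
the tissue-to-plasma partition coefficients (Kp) for the 13 model tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import yaml

from .physiology import TISSUES

APIS = ("RIF", "ETH", "MOX")


class ParameterError(ValueError):
    """A compound parameter block violates its invariants."""


@dataclass(frozen=True)
class CompoundParams:
    name: str
    dose_mg: float
    therapeutic_oral_dose_mg: float
    mw_free: float
    mw_salt: float
    bp_ratio: float
    fu: float
    vdss_L_per_kg: float
    peff_1e4_cm_per_s: float
    cl_iv_L_per_h: float
    cl_r_L_per_h: float
    kp: Mapping[str, float]
    kp_scale: float = 1.0  # bookkeeping: factor applied by rescale_kp_to_vdss

    def __post_init__(self) -> None:
        if not (0.0 < self.fu <= 1.0):
            raise ParameterError("fu must lie in (0, 1]")
        if self.cl_r_L_per_h > self.cl_iv_L_per_h:
            raise ParameterError("renal clearance cannot exceed systemic clearance")
        if self.mw_salt < self.mw_free:
            raise ParameterError("salt MW cannot be below free-form MW")
        if set(self.kp) != set(TISSUES):
            missing = set(TISSUES) - set(self.kp)
            extra = set(self.kp) - set(TISSUES)
            raise ParameterError(f"kp must cover the model tissues (missing={sorted(missing)}, extra={sorted(extra)})")
        if any(v <= 0 for v in self.kp.values()):
            raise ParameterError("all Kp values must be > 0")
        for f in ("dose_mg", "bp_ratio", "vdss_L_per_kg", "peff_1e4_cm_per_s", "cl_iv_L_per_h"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"{f} must be > 0")

    def with_kp(self, kp: Mapping[str, float], scale: float) -> "CompoundParams":
        return replace(self, kp=dict(kp), kp_scale=scale)


def load_compound(name: str) -> CompoundParams:
    """Load one API's shipped parameter file (``RIF``, ``ETH`` or ``MOX``)."""
    key = name.lower()
    if key.upper() not in APIS:
        raise KeyError(f"unknown API {name!r}; expected one of {APIS}")
    text = resources.files("tbinhale.data.compounds").joinpath(f"{key}.yaml").read_text()
    return compound_from_dict(yaml.safe_load(text))


def compound_from_dict(d: dict) -> CompoundParams:
    return CompoundParams(
        name=d["name"],
        dose_mg=float(d["dose_mg"]),
        therapeutic_oral_dose_mg=float(d["therapeutic_oral_dose_mg"]),
        mw_free=float(d["mw_free"]),
        mw_salt=float(d["mw_salt"]),
        bp_ratio=float(d["bp_ratio"]),
        fu=float(d["fu"]),
        vdss_L_per_kg=float(d["vdss_L_per_kg"]),
        peff_1e4_cm_per_s=float(d["peff_1e4_cm_per_s"]),
        cl_iv_L_per_h=float(d["cl_iv_L_per_h"]),
        cl_r_L_per_h=float(d["cl_r_L_per_h"]),
        kp={k: float(v) for k, v in d["kp"].items()},
    )


def load_observed_pk() -> dict:
    """Observed clinical Cmax/AUC reference values per API."""
    text = resources.files("tbinhale.data").joinpath("observed_pk.yaml").read_text()
    return yaml.safe_load(text)
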