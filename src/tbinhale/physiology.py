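"""Virtual-subject physiology for the whole-body PBPK model.

A :class:`VirtualSubject` (anthropometrics) is combined with a reference-human
parameter table to produce a fully determined :class:`PhysiologyTable` of
tissue volumes and regional blood flows.  Scaling is deliberately minimal:
tissue and blood volumes scale linearly with body weight, cardiac output
scales allometrically (weight^0.75), and each tissue's flow is a fixed
fraction of cardiac output.  Height and age enter only through the choice of
subject, and all subjects are built as male (the simulations use a single
male virtual individual per compound).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

#: The 13 perfusion-limited tissue compartments, in canonical order.
TISSUES = (
    "Lung", "Adipose", "Muscle", "Liver", "Spleen", "Heart", "Brain",
    "Kidney", "Skin", "ReproOrg", "RedMarrow", "YellowMarrow", "RestOfBody",
)


class ConfigurationError(ValueError):
    """A reference parameter set is incomplete or inconsistent."""


@dataclass(frozen=True)
class VirtualSubject:
    """Anthropometrics of one virtual individual."""

    age_years: float
    body_weight_kg: float
    body_height_cm: float
    sex: str = "male"
    label: str = ""

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if self.body_height_cm <= 0:
            raise ValueError("body_height_cm must be > 0")
        if self.age_years <= 0:
            raise ValueError("age_years must be > 0")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


@dataclass(frozen=True)
class PhysiologyTable:
    """Tissue volumes (L), regional blood flows (L/h) and blood pools.

    ``blood_flows`` are arterial inflows per tissue; the liver entry is its
    arterial inflow only (hepatic artery plus the splanchnic bed routed with
    it), with the portal contribution arriving as the outflow of the
    ``portal_inflow_tissues``.  The lung receives the whole cardiac output in
    series between the venous and arterial pools.
    """

    body_weight_kg: float
    tissue_volumes: Mapping[str, float]
    blood_flows: Mapping[str, float]
    cardiac_output_L_per_h: float
    venous_blood_L: float
    arterial_blood_L: float
    hematocrit: float
    portal_inflow_tissues: frozenset = field(default_factory=frozenset)

    @property
    def plasma_volume_L(self) -> float:
        return (self.venous_blood_L + self.arterial_blood_L) * (1.0 - self.hematocrit)

    @property
    def lung_volume_L(self) -> float:
        return self.tissue_volumes["Lung"]

    @property
    def hepatic_artery_flow_L_per_h(self) -> float:
        return self.blood_flows["Liver"]

    @property
    def liver_outflow_L_per_h(self) -> float:
        """Total (arterial + portal) blood flow leaving the liver."""
        return self.blood_flows["Liver"] + sum(
            self.blood_flows[t] for t in self.portal_inflow_tissues
        )

    def validate(self) -> None:
        for name in TISSUES:
            if self.tissue_volumes.get(name, 0.0) <= 0:
                raise ConfigurationError(f"non-positive volume for tissue {name!r}")
            if self.blood_flows.get(name, 0.0) <= 0:
                raise ConfigurationError(f"non-positive flow for tissue {name!r}")
        co = self.cardiac_output_L_per_h
        inflow = sum(self.blood_flows[t] for t in TISSUES if t != "Lung")
        if abs(inflow - co) > 1e-9 * co:
            raise ConfigurationError(
                f"tissue inflows ({inflow:.6f} L/h) do not balance cardiac output ({co:.6f} L/h)"
            )
        if abs(self.blood_flows["Lung"] - co) > 1e-9 * co:
            raise ConfigurationError("lung flow must equal cardiac output")


def load_reference(name: str = "reference_human.yaml") -> dict:
    """Load the shipped reference-human parameter set."""
    text = resources.files("tbinhale.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def build_physiology(subject: VirtualSubject, reference: dict | None = None) -> PhysiologyTable:
    """Scale a reference-human table to one subject.

    Volumes scale linearly with body weight; cardiac output scales with
    weight^0.75; each tissue flow is its reference fraction of the scaled
    cardiac output, so flow balance holds by construction.
    """
    ref = reference if reference is not None else load_reference()
    tissues = ref["tissues"]
    missing = [t for t in TISSUES if t not in tissues]
    if missing:
        raise ConfigurationError(f"reference set missing tissue(s): {', '.join(missing)}")

    w_ref = float(ref["reference_body_weight_kg"])
    f_vol = subject.body_weight_kg / w_ref
    co = float(ref["cardiac_output_L_per_h"]) * (subject.body_weight_kg / w_ref) ** 0.75

    fractions = {t: float(tissues[t]["flow_fraction_of_co"]) for t in TISSUES}
    total = sum(f for t, f in fractions.items() if t != "Lung")
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"reference flow fractions (lung excluded) sum to {total}, expected 1.0"
        )

    volumes = {t: float(tissues[t]["volume_L"]) * f_vol for t in TISSUES}
    flows = {t: fractions[t] * co for t in TISSUES}
    table = PhysiologyTable(
        body_weight_kg=subject.body_weight_kg,
        tissue_volumes=volumes,
        blood_flows=flows,
        cardiac_output_L_per_h=co,
        venous_blood_L=float(ref["venous_blood_L"]) * f_vol,
        arterial_blood_L=float(ref["arterial_blood_L"]) * f_vol,
        hematocrit=float(ref["hematocrit"]),
        portal_inflow_tissues=frozenset(ref.get("portal_inflow_tissues", ["Spleen"])),
    )
    table.validate()
    return table


#: Mean anthropometrics of the clinical study populations backing each
#: compound's trial simulation.  All virtual subjects are built as male.
_STUDY_SUBJECTS = {
    "RIF": VirtualSubject(30.0, 85.5, 176.4, "male", "RIF study population"),
    "ETH": VirtualSubject(39.1, 79.3, 172.6, "male", "ETH study population"),
    "MOX": VirtualSubject(33.6, 81.5, 182.2, "male", "MOX study population"),
}


def study_subject(api_name: str) -> VirtualSubject:
    """Return the study-population mean anthropometrics for one API."""
    try:
        return replace(_STUDY_SUBJECTS[api_name.upper()])
    except KeyError:
        raise KeyError(
            f"unknown API {api_name!r}; expected one of {sorted(_STUDY_SUBJECTS)}"
        ) from None
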