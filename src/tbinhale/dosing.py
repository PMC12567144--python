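"""Dose translation: lung exposure → inhaled dose → molar ratios → capsules.

The lung-exposure metric is taken exactly as defined for the oral PBPK
simulations:  AUC0-inf of the lung-tissue concentration profile (µg·h/mL)
times the lung tissue volume (mL), divided by the administered dose (µg),
times 100.  It is treated as a percentage label (its literal units are
hours×100) and serves as a surrogate for pulmonary targeting efficiency.
The inhaled dose at a fixed fine-particle fraction follows

    inhaled dose = oral dose × lung exposure% / FPF%

and fixed-dose-combination molar ratios are computed from the dosed salt
forms' molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nca import NCAInputError, nca
from .pbpk import ConcentrationProfile
from .physiology import PhysiologyTable


@dataclass(frozen=True)
class DosePlan:
    api: str
    oral_dose_mg: float
    lung_exposure_percent: float
    fpf_percent: float
    inhaled_dose_mg: float
    source: str  # "model" or "literature-tenth-rule"


@dataclass(frozen=True)
class MolarRatioResult:
    api_a: str
    api_b: str
    dose_a_mg: float
    dose_b_mg: float
    mw_a: float
    mw_b: float
    ratio_b_per_a: float

    def formatted(self, decimals: int | None = None) -> str:
        """Quote as ``1:r``; default is 3 significant figures."""
        if decimals is None:
            return f"1:{self.ratio_b_per_a:.3g}"
        return f"1:{self.ratio_b_per_a:.{decimals}f}"


@dataclass(frozen=True)
class CapsuleComposition:
    fill_mass_mg: float
    ratio_b_per_a: float
    mass_a_mg: float
    mass_b_mg: float


def lung_exposure(profile: ConcentrationProfile, phys: PhysiologyTable) -> float:
    """Percent of the administered dose retained in the lung over time.

    AUC0-inf(lung) × V_lung(mL) / dose(µg) × 100, with the lung AUC
    extrapolated by NCA on the simulated lung-tissue series.
    """
    if "Lung" not in profile.tissue_ug_per_mL:
        raise NCAInputError("profile has no lung tissue series")
    if profile.dose_ug <= 0:
        raise NCAInputError("administered dose must be > 0")
    res = nca(profile.times_h, profile.tissue_ug_per_mL["Lung"])
    if res.auc_0_inf is None:
        raise NCAInputError("lung AUC0-inf unavailable (no terminal slope)")
    v_lung_mL = phys.lung_volume_L * 1000.0
    return res.auc_0_inf * v_lung_mL / profile.dose_ug * 100.0


def inhaled_dose(oral_dose_mg: float, lung_exposure_percent: float,
                 fpf_percent: float = 40.0, api: str = "") -> DosePlan:
    """Model-based inhaled dose at a fixed fine-particle fraction."""
    if fpf_percent <= 0 or fpf_percent > 100:
        raise ValueError("FPF must lie in (0, 100]")
    if oral_dose_mg <= 0 or lung_exposure_percent <= 0:
        raise ValueError("oral dose and lung exposure must be > 0")
    dose = oral_dose_mg * lung_exposure_percent / fpf_percent
    return DosePlan(api, oral_dose_mg, lung_exposure_percent, fpf_percent, dose, "model")


def tenth_rule_dose(oral_dose_mg: float, api: str = "") -> DosePlan:
    """Literature rule of thumb: the inhaled dose is one tenth of the oral dose."""
    if oral_dose_mg <= 0:
        raise ValueError("oral dose must be > 0")
    return DosePlan(api, oral_dose_mg, float("nan"), float("nan"),
                    oral_dose_mg / 10.0, "literature-tenth-rule")


def molar_ratio(dose_a_mg: float, mw_a: float, dose_b_mg: float, mw_b: float,
                api_a: str = "A", api_b: str = "B") -> MolarRatioResult:
    """API:API molar ratio 1:r with r = (dose_b/mw_b)/(dose_a/mw_a).

    Doses and molecular weights must refer consistently to the dosed salt
    forms.
    """
    if min(dose_a_mg, mw_a, dose_b_mg, mw_b) <= 0:
        raise ValueError("doses and molecular weights must be > 0")
    r = (dose_b_mg / mw_b) / (dose_a_mg / mw_a)
    return MolarRatioResult(api_a, api_b, dose_a_mg, dose_b_mg, mw_a, mw_b, r)


def dose_per_100mg(conc_ug_per_g: float, dose_mg: float) -> float:
    """Normalize a tissue concentration to a 100-mg administered dose."""
    if conc_ug_per_g < 0 or dose_mg <= 0:
        raise ValueError("concentration must be >= 0 and dose > 0")
    return conc_ug_per_g * 100.0 / dose_mg


def tissue_ratio_check(conc_a_per_100mg: float, mw_a: float,
                       conc_b_per_100mg: float, mw_b: float) -> float:
    """Molecular B/A ratio of dose-normalized tissue concentrations.

    Independent literature-based check of the simulated exposure ratios:
    concentrations per 100-mg dose are converted to moles (free-base MWs)
    and ratioed.
    """
    if min(conc_a_per_100mg, mw_a, conc_b_per_100mg, mw_b) <= 0:
        raise ValueError("inputs must be > 0")
    return (conc_b_per_100mg / mw_b) / (conc_a_per_100mg / mw_a)


def capsule_composition(fill_mass_mg: float = 25.0, ratio_b_per_a: float = 1.0,
                        mw_a: float = 1.0, mw_b: float = 1.0) -> CapsuleComposition:
    """Split a capsule fill mass between two APIs at a fixed molar ratio.

    mass_a = fill × mw_a / (mw_a + r·mw_b); the remainder is API B, so the
    masses sum to the fill mass exactly.
    """
    if fill_mass_mg <= 0 or mw_a <= 0 or mw_b <= 0 or ratio_b_per_a < 0:
        raise ValueError("fill mass and MWs must be > 0, ratio >= 0")
    mass_a = fill_mass_mg * mw_a / (mw_a + ratio_b_per_a * mw_b)
    return CapsuleComposition(fill_mass_mg, ratio_b_per_a, mass_a, fill_mass_mg - mass_a)
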