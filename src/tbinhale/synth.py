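"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: noisy oral
plasma profiles from closed-form linear PK models, impactor stage-mass
tables constructed by inverting the aerosol-metric formulas, and
dissolution sampling series with exact withdrawal/replacement bookkeeping.
All generators are deterministic under a fixed seed, and noiseless
generation composed with the corresponding analysis operation is the
identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aerosol import DissolutionRun, ImpactorRun


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Closed-form oral PK models


def one_compartment_oral(t, dose, ka, cl, v, f=1.0):
    """Bateman profile C(t) = F·D·ka / (V(ka-ke)) (e^{-ke t} - e^{-ka t})."""
    t = np.asarray(t, dtype=float)
    ke = cl / v
    if abs(ka - ke) < 1e-12 * ka:
        return f * dose * ka * t * np.exp(-ka * t) / v
    return f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def two_compartment_oral(t, dose, ka, cl, v1, v2, q, f=1.0):
    """Bi-exponential disposition with first-order absorption."""
    t = np.asarray(t, dtype=float)
    k10, k12, k21 = cl / v1, q / v1, q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    lam1, lam2 = (s + disc) / 2.0, (s - disc) / 2.0
    coeff = f * dose * ka / v1
    out = np.zeros_like(t)
    for lam in (lam1, lam2):
        num = (k21 - lam) * np.exp(-lam * t)
        den = (ka - lam) * ((lam1 if lam is lam2 else lam2) - lam)
        out = out + num / den
    out = out + (k21 - ka) * np.exp(-ka * t) / ((lam1 - ka) * (lam2 - ka))
    return coeff * out


@dataclass(frozen=True)
class SyntheticPKSpec:
    """Specification of one synthetic oral PK study."""

    model: str = "one-compartment-oral"  # or "two-compartment-oral"
    dose: float = 100.0                  # same mass unit as concentrations·volume
    ka_per_h: float = 1.0
    cl_L_per_h: float = 5.0
    v_L: float = 25.0                    # V (1-cpt) or V1 (2-cpt)
    v2_L: float = 50.0
    q_L_per_h: float = 10.0
    f: float = 1.0
    times_h: tuple = tuple(np.arange(0.0, 24.001, 0.25))
    cv_percent: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("one-compartment-oral", "two-compartment-oral"):
            raise SpecError(f"unknown model {self.model!r}")
        if self.cv_percent < 0:
            raise SpecError("CV must be >= 0")


def generate_pk_profile(spec: SyntheticPKSpec) -> tuple[pd.DataFrame, dict]:
    """Closed-form profile times proportional lognormal noise, plus truth.

    The noise multiplier is exp(sigma·Z) with sigma chosen so the
    multiplicative CV equals ``cv_percent`` and E[multiplier] = 1.
    """
    t = np.asarray(spec.times_h, dtype=float)
    if spec.model == "one-compartment-oral":
        c = one_compartment_oral(t, spec.dose, spec.ka_per_h, spec.cl_L_per_h,
                                 spec.v_L, spec.f)
    else:
        c = two_compartment_oral(t, spec.dose, spec.ka_per_h, spec.cl_L_per_h,
                                 spec.v_L, spec.v2_L, spec.q_L_per_h, spec.f)
    cv = spec.cv_percent / 100.0
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        rng = np.random.default_rng(spec.seed)
        noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=t.shape))
        obs = c * noise
    else:
        obs = c.copy()
    truth = {
        "model": spec.model,
        "auc_0_inf": spec.f * spec.dose / spec.cl_L_per_h,
        "clearance": spec.cl_L_per_h,
        "ka_per_h": spec.ka_per_h,
        "dose": spec.dose,
        "f": spec.f,
    }
    return pd.DataFrame({"time_h": t, "conc": obs}), truth


# ---------------------------------------------------------------------------
# Impactor runs


@dataclass(frozen=True)
class SyntheticImpactorSpec:
    ef_target_percent: float = 75.0
    fpf_target_percent: float = 55.6
    recovered_dose_ug: float = 30000.0
    induction_fraction: float = 0.5  # split of coarse impactor mass: induction vs preseparator
    noise_sd_fraction: float = 0.0   # additive Gaussian SD as fraction of recovered dose
    seed: int = 0
    api: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.ef_target_percent <= 100.0):
            raise SpecError("EF target must lie in [0, 100]")
        if not (0.0 <= self.fpf_target_percent <= 100.0):
            raise SpecError("FPF target must lie in [0, 100]")
        if self.recovered_dose_ug <= 0:
            raise SpecError("recovered dose must be > 0")
        if not (0.0 <= self.induction_fraction <= 1.0):
            raise SpecError("induction_fraction must lie in [0, 1]")


def generate_impactor_run(spec: SyntheticImpactorSpec) -> ImpactorRun:
    """Stage masses hitting the EF/FPF targets exactly, then perturbed.

    Inversion: emitted = EF/100·recovered (the emitted dose equals the mass
    reaching the impactor), FPM = FPF/100·emitted, and the coarse remainder
    splits between induction port and preseparator.  With zero noise,
    ``aerosol_metrics`` on the result returns the targets exactly.
    """
    r = spec.recovered_dose_ug
    emitted = spec.ef_target_percent / 100.0 * r
    device = r - emitted
    fpm = spec.fpf_target_percent / 100.0 * emitted
    if emitted == 0.0 and spec.fpf_target_percent > 0:
        raise SpecError("FPF target > 0 infeasible with EF target 0")
    coarse = emitted - fpm
    stages = np.array([
        device,
        coarse * spec.induction_fraction,
        coarse * (1.0 - spec.induction_fraction),
        fpm,
    ])
    if spec.noise_sd_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        stages = stages + rng.normal(0.0, spec.noise_sd_fraction * r, size=4)
        stages = np.clip(stages, 0.0, None)  # truncated at zero
    return ImpactorRun(
        inhaler_capsule_ug=float(stages[0]),
        induction_port_ug=float(stages[1]),
        preseparator_ug=float(stages[2]),
        filter_ug=float(stages[3]),
        api=spec.api,
    )


# ---------------------------------------------------------------------------
# Dissolution runs with exact withdrawal bookkeeping


def first_order_release(k_per_min: float):
    """Fraction released over time: 1 - e^{-k t}."""
    def frac(t):
        return 1.0 - np.exp(-k_per_min * np.asarray(t, dtype=float))
    return frac


def generate_dissolution_run(
    release_fraction,
    dose_ug: float,
    times_min=(0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 120.0, 180.0),
    vessel_volume_mL: float = 55.0,
    sample_volume_mL: float = 1.0,
    api: str = "",
) -> DissolutionRun:
    """Simulate sampled concentrations including aliquot depletion exactly.

    ``release_fraction(t)`` is the cumulative fraction of ``dose_ug``
    dissolved by time t (monotone, ≤ 1).  At every sample the aliquot
    removes C·v of drug and is replaced by fresh medium; the next sampled
    concentration therefore reflects all earlier withdrawals.  This is the
    exact oracle for the replacement correction in
    :func:`tbinhale.aerosol.dissolution_profile`.
    """
    t = np.asarray(times_min, dtype=float)
    rel = np.asarray(release_fraction(t), dtype=float)
    if np.any(np.diff(rel) < -1e-12):
        raise SpecError("release curve must be monotone non-decreasing")
    if np.any(rel > 1.0 + 1e-12):
        raise SpecError("release fraction exceeds the dose")
    conc = np.zeros_like(t)
    removed = 0.0
    for i in range(t.size):
        in_vessel = rel[i] * dose_ug - removed
        conc[i] = in_vessel / vessel_volume_mL
        removed += conc[i] * sample_volume_mL
    return DissolutionRun(
        times_min=t, sampled_conc_ug_per_mL=conc, dose_ug=dose_ug,
        vessel_volume_mL=vessel_volume_mL, sample_volume_mL=sample_volume_mL,
        api=api,
    )
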