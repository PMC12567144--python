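"""Formulation analytics: impactor metrics, content uniformity, particle-size
summaries and dissolution with sampling-volume correction.

The fast-screening impactor splits an emitted aerosol at a 5-µm aerodynamic
cut-off: mass landing on the fine-fraction filter is the fine particle mass
(FPM).  The emitted fraction (EF) is the impactor-recovered mass (induction
port + preseparator + filter) over the total recovered dose, and the fine
particle fraction (FPF) is FPM over the emitted dose.  Dissolution sampling
withdraws a fixed aliquot at each time point and replaces it with fresh
medium, so the cumulative dissolved amount must be corrected for the drug
removed with earlier aliquots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


class InconsistencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cascade/fast-screening impactor metrics

IMPACTOR_STAGES = ("inhaler_capsule", "induction_port", "preseparator", "filter")


@dataclass(frozen=True)
class ImpactorRun:
    """Per-stage deposited masses (µg) for one API in one actuation series."""

    inhaler_capsule_ug: float
    induction_port_ug: float  # mouthpiece + induction port
    preseparator_ug: float
    filter_ug: float
    api: str = ""
    flow_L_per_min: float = 60.0
    actuation_s: float = 4.0
    fill_mass_mg: float = 25.0

    def __post_init__(self) -> None:
        for s in IMPACTOR_STAGES:
            if getattr(self, f"{s}_ug") < 0:
                raise InputError(f"stage mass {s} must be >= 0")
        if self.recovered_ug <= 0:
            raise InputError("recovered dose must be > 0")

    @property
    def recovered_ug(self) -> float:
        return (self.inhaler_capsule_ug + self.induction_port_ug
                + self.preseparator_ug + self.filter_ug)


@dataclass(frozen=True)
class AerosolMetrics:
    ef_percent: float
    fpf_percent: float
    fpm_mg: float
    emitted_dose_mg: float
    recovered_dose_mg: float
    api: str = ""


def aerosol_metrics(run: ImpactorRun, include_preseparator: bool = True) -> AerosolMetrics:
    """EF / FPF / FPM from one impactor run.

    EF uses the total recovered dose as denominator and FPF the emitted
    dose, both as defined for the fast-screening impactor.  The
    preseparator is counted in the impactor (emitted) mass by default; the
    toggle exists because some protocols list it with the device.
    """
    recovered = run.recovered_ug
    impactor = run.induction_port_ug + run.filter_ug
    if include_preseparator:
        impactor += run.preseparator_ug
    emitted = recovered - run.inhaler_capsule_ug
    fpm = run.filter_ug
    ef = 100.0 * impactor / recovered
    if emitted <= 0:
        if fpm > 0:
            raise InconsistencyError("zero emitted dose but non-zero filter mass")
        warnings.warn("zero emitted dose; FPF reported as 0", stacklevel=2)
        fpf = 0.0
    else:
        fpf = 100.0 * fpm / emitted
    return AerosolMetrics(
        ef_percent=ef, fpf_percent=fpf, fpm_mg=fpm / 1000.0,
        emitted_dose_mg=emitted / 1000.0, recovered_dose_mg=recovered / 1000.0,
        api=run.api,
    )


def impactor_run_from_csv(path, api: str | None = None) -> ImpactorRun:
    """Read one impactor run from a ``stage,api,mass_ug`` CSV."""
    df = pd.read_csv(path)
    required = {"stage", "api", "mass_ug"}
    if df.empty or not required.issubset(df.columns):
        raise InputError(f"impactor CSV needs columns {sorted(required)}")
    if api is not None:
        df = df[df["api"] == api]
    masses = dict(zip(df["stage"], df["mass_ug"]))
    unknown = set(masses) - set(IMPACTOR_STAGES)
    if unknown:
        raise InputError(f"unknown impactor stage(s): {sorted(unknown)}")
    return ImpactorRun(
        inhaler_capsule_ug=float(masses.get("inhaler_capsule", 0.0)),
        induction_port_ug=float(masses.get("induction_port", 0.0)),
        preseparator_ug=float(masses.get("preseparator", 0.0)),
        filter_ug=float(masses.get("filter", 0.0)),
        api=api or (df["api"].iloc[0] if len(df) else ""),
    )


# ---------------------------------------------------------------------------
# Content uniformity


@dataclass(frozen=True)
class ContentUniformity:
    mean_percent: float
    sd_percent: float
    rsd_percent: float
    uniformity_pass: bool  # mean within 100 ± 15 % of label claim
    homogeneity_pass: bool  # RSD below 5 %
    n: int


def content_uniformity(samples_percent_of_label,
                       uniformity_limit: float = 15.0,
                       rsd_limit: float = 5.0) -> ContentUniformity:
    """Mean ± sample SD of assayed contents and the two pass criteria."""
    x = np.asarray(samples_percent_of_label, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 assayed samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    rsd = 100.0 * sd / mean
    return ContentUniformity(
        mean_percent=mean, sd_percent=sd, rsd_percent=rsd,
        uniformity_pass=bool(abs(mean - 100.0) <= uniformity_limit),
        homogeneity_pass=bool(rsd < rsd_limit),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Particle-size distribution summaries


@dataclass(frozen=True)
class PSDSummary:
    x10_um: float
    x50_um: float
    x90_um: float
    span: float
    smd_um: float
    frac_below_5um_percent: float


def psd_summary(bin_edges_um, volume_fractions) -> PSDSummary:
    """Quantiles, span, Sauter mean diameter and %<5 µm of a binned PSD.

    Quantiles interpolate the cumulative curve linearly over the bin edges;
    the Sauter mean diameter uses geometric-mean bin diameters,
    SMD = 1 / sum(f_i / d_i).
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    frac = np.asarray(volume_fractions, dtype=float)
    if edges.ndim != 1 or edges.size != frac.size + 1:
        raise InputError("need n+1 bin edges for n fractions")
    if np.any(np.diff(edges) < 0) or edges[0] < 0:
        raise InputError("bin edges must be sorted and non-negative")
    if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-6:
        raise InputError("fractions must be non-negative and sum to 1")

    cum = np.concatenate([[0.0], np.cumsum(frac)])
    cum[-1] = 1.0

    def quantile(q):
        return float(np.interp(q, cum, edges))

    x10, x50, x90 = quantile(0.10), quantile(0.50), quantile(0.90)
    d_geo = np.sqrt(edges[:-1] * edges[1:])
    d_geo = np.where(d_geo > 0, d_geo, (edges[:-1] + edges[1:]) / 2.0)
    if np.any((frac > 0) & (d_geo <= 0)):
        raise InputError("bins with mass must have positive diameters")
    smd = 1.0 / float(np.sum(frac / d_geo))
    below5 = 100.0 * float(np.interp(5.0, edges, cum))
    return PSDSummary(
        x10_um=x10, x50_um=x50, x90_um=x90,
        span=(x90 - x10) / x50, smd_um=smd,
        frac_below_5um_percent=below5,
    )


def span_from_quantiles(x10: float, x50: float, x90: float) -> float:
    """(x90 - x10)/x50 for quantiles reported by a particle sizer."""
    if not (0 < x10 <= x50 <= x90):
        raise InputError("quantiles must satisfy 0 < x10 <= x50 <= x90")
    return (x90 - x10) / x50


def psd_from_csv(path) -> PSDSummary:
    """Read a binned PSD from a ``bin_lo_um,bin_hi_um,fraction`` CSV."""
    df = pd.read_csv(path)
    required = {"bin_lo_um", "bin_hi_um", "fraction"}
    if df.empty or not required.issubset(df.columns):
        raise InputError(f"PSD CSV needs columns {sorted(required)}")
    lo, hi = df["bin_lo_um"].to_numpy(float), df["bin_hi_um"].to_numpy(float)
    if np.any(lo[1:] != hi[:-1]):
        raise InputError("PSD bins must be contiguous")
    edges = np.concatenate([lo, hi[-1:]])
    return psd_summary(edges, df["fraction"].to_numpy(float))


# ---------------------------------------------------------------------------
# Dissolution with sampling-volume correction

DISSOLUTION_TIMES_MIN = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 120.0, 180.0)


@dataclass(frozen=True)
class DissolutionRun:
    """Sampled concentrations from a constant-volume dissolution test."""

    times_min: np.ndarray
    sampled_conc_ug_per_mL: np.ndarray
    dose_ug: float
    vessel_volume_mL: float = 55.0
    sample_volume_mL: float = 1.0
    api: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, float)
        c = np.asarray(self.sampled_conc_ug_per_mL, float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "sampled_conc_ug_per_mL", c)
        if t.shape != c.shape or t.ndim != 1:
            raise InputError("times and concentrations must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InputError("sampling times must be strictly increasing")
        if self.sample_volume_mL >= self.vessel_volume_mL:
            raise InputError("sample volume must be below vessel volume")
        if self.sample_volume_mL < 0:
            raise InputError("sample volume must be >= 0")


def dissolution_profile(run: DissolutionRun) -> pd.DataFrame:
    """Cumulative percent dissolved, corrected for medium replacement.

    The cumulative amount at sample n is C_n·V + v·sum_{i<n} C_i — the drug
    currently in the vessel plus everything carried away by earlier aliquots
    (each aliquot of volume v removed C_i·v and was replaced with fresh
    medium).  A declining corrected series warns rather than fails, since
    in-vessel degradation produces exactly that signature.
    """
    if run.dose_ug <= 0:
        raise InputError("theoretical dose must be > 0")
    c = run.sampled_conc_ug_per_mL
    removed = np.concatenate([[0.0], np.cumsum(c[:-1]) * run.sample_volume_mL])
    amount = c * run.vessel_volume_mL + removed
    percent = 100.0 * amount / run.dose_ug
    if np.any(np.diff(percent) < -1e-9):
        warnings.warn("corrected dissolution series is not monotone "
                      "(possible in-vessel degradation)", stacklevel=2)
    return pd.DataFrame({
        "time_min": run.times_min,
        "sampled_conc_ug_per_mL": c,
        "cumulative_amount_ug": amount,
        "percent_dissolved": percent,
    })


def dissolution_run_from_csv(path, dose_ug: float,
                             vessel_volume_mL: float = 55.0,
                             sample_volume_mL: float = 1.0) -> DissolutionRun:
    """Read sampled concentrations from a ``time_min,conc_ug_per_mL`` CSV."""
    df = pd.read_csv(path)
    required = {"time_min", "conc_ug_per_mL"}
    if df.empty or not required.issubset(df.columns):
        raise InputError(f"dissolution CSV needs columns {sorted(required)}")
    return DissolutionRun(
        times_min=df["time_min"].to_numpy(float),
        sampled_conc_ug_per_mL=df["conc_ug_per_mL"].to_numpy(float),
        dose_ug=dose_ug, vessel_volume_mL=vessel_volume_mL,
        sample_volume_mL=sample_volume_mL,
    )
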