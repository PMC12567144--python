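"""End-to-end orchestration: oral PBPK simulation → validation → lung
exposure → inhaled doses → molar ratios → capsule compositions, and the
formulation-analytics report over impactor/PSD/dissolution inputs.

Everything here is a thin, reproducible driver over the library modules;
re-running with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import aerosol, dosing, nca, pbpk, physiology
from .compounds import APIS, CompoundParams, compound_from_dict, load_compound, load_observed_pk

log = logging.getLogger("tbinhale")

#: Dose-translation pairs: (API A, API B) for the 1:r fixed-dose combinations.
PAIRS = (("RIF", "ETH"), ("RIF", "MOX"))


@dataclass(frozen=True)
class PipelineConfig:
    compound_files: tuple = ()          # empty -> shipped RIF/ETH/MOX tables
    subject_source: str = "study"       # "study" or "custom"
    custom_subjects: Mapping[str, physiology.VirtualSubject] | None = None
    fpf_percent: float = 40.0
    capsule_fill_mg: float = 25.0
    horizon_h: float = 72.0
    grid_h: float = 0.05
    validation_threshold_percent: float = 20.0
    #: if given, dose plans use these lung exposures (percent, keyed by API)
    #: instead of the simulated ones — e.g. to rebuild published dose tables.
    lung_exposure_override: Mapping[str, float] | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fpf_percent <= 100.0):
            raise ValueError("FPF must lie in (0, 100]")
        for f in self.compound_files:
            if not Path(f).exists():
                raise FileNotFoundError(f)


def config_from_yaml(path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        compound_files=tuple(d.get("compound_files", ())),
        subject_source=d.get("subject_source", "study"),
        fpf_percent=float(d.get("fpf_percent", 40.0)),
        capsule_fill_mg=float(d.get("capsule_fill_mg", 25.0)),
        horizon_h=float(d.get("horizon_h", 72.0)),
        grid_h=float(d.get("grid_h", 0.05)),
        validation_threshold_percent=float(d.get("validation_threshold_percent", 20.0)),
        lung_exposure_override=d.get("lung_exposure_override"),
        output_dir=d.get("output_dir"),
        seed=int(d.get("seed", 0)),
    )


def _load_compounds(config: PipelineConfig) -> dict[str, CompoundParams]:
    if config.compound_files:
        out = {}
        for f in config.compound_files:
            params = compound_from_dict(yaml.safe_load(Path(f).read_text()))
            out[params.name] = params
        return out
    return {api: load_compound(api) for api in APIS}


def _subject_for(api: str, config: PipelineConfig) -> physiology.VirtualSubject:
    if config.subject_source == "custom" and config.custom_subjects:
        return config.custom_subjects[api]
    return physiology.study_subject(api)


def _params_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class DoseTranslationReport:
    profiles: Mapping[str, pbpk.ConcentrationProfile]
    pk_table: pd.DataFrame
    validation: nca.ValidationReport
    dose_plans: pd.DataFrame
    molar_ratios: pd.DataFrame
    capsules: pd.DataFrame
    lung_exposure_percent: Mapping[str, float]
    kp_scales: Mapping[str, float]

    @property
    def exit_status(self) -> int:
        return 0 if self.validation.overall_pass else 1


def simulate_api(params: CompoundParams, subject: physiology.VirtualSubject,
                 horizon_h: float = 72.0, grid_h: float = 0.05,
                 dose_mg: float | None = None):
    """One API's full simulation chain: physiology → Kp rescale → simulate."""
    phys = physiology.build_physiology(subject)
    scaled = pbpk.rescale_kp_to_vdss(params, phys)
    absorption = pbpk.absorption_from_peff(params.peff_1e4_cm_per_s)
    profile = pbpk.simulate(scaled, phys, absorption, horizon_h=horizon_h,
                            grid_h=grid_h, dose_mg=dose_mg)
    return profile, phys, scaled


def run_dose_translation(config: PipelineConfig | None = None) -> DoseTranslationReport:
    """The full oral-to-inhaled translation workflow for all configured APIs."""
    config = config or PipelineConfig()
    compounds = _load_compounds(config)
    observed = load_observed_pk()

    profiles, exposures, kp_scales, sim_metrics = {}, {}, {}, {}
    for api, params in compounds.items():
        log.info("simulate %s params=%s", api, _params_hash(params))
        profile, phys, scaled = simulate_api(
            params, _subject_for(api, config),
            horizon_h=config.horizon_h, grid_h=config.grid_h,
        )
        pbpk.check_mass_balance(profile)
        profiles[api] = profile
        kp_scales[api] = scaled.kp_scale
        exposures[api] = dosing.lung_exposure(profile, phys)

    pk_table = pbpk.simulated_pk_table(profiles)
    for api in compounds:
        sim_metrics[api] = {
            "cmax": float(pk_table.loc[api, "cmax"]),
            "auc_0_inf": float(pk_table.loc[api, "auc_0_inf"]),
        }
    obs_gate = {
        api: {m: observed[api][m] for m in ("cmax", "auc_0_inf")}
        for api in compounds if api in observed
    }
    validation = nca.validate_model(obs_gate, sim_metrics,
                                    threshold_percent=config.validation_threshold_percent)
    log.info("validation max %%PE = %.2f (%s)", validation.max_pe_percent,
             "pass" if validation.overall_pass else "FAIL")

    plan_exposures = dict(exposures)
    if config.lung_exposure_override:
        plan_exposures.update(config.lung_exposure_override)

    plan_rows = []
    plans: dict[tuple[str, str], dosing.DosePlan] = {}
    for api, params in compounds.items():
        model_plan = dosing.inhaled_dose(params.therapeutic_oral_dose_mg,
                                         plan_exposures[api], config.fpf_percent, api=api)
        lit_plan = dosing.tenth_rule_dose(params.therapeutic_oral_dose_mg, api=api)
        plans[(api, "model")] = model_plan
        plans[(api, "literature")] = lit_plan
        plan_rows.append({
            "api": api,
            "oral_dose_mg": params.therapeutic_oral_dose_mg,
            "lung_exposure_percent": plan_exposures[api],
            "fpf_percent": config.fpf_percent,
            "inhaled_dose_model_mg": model_plan.inhaled_dose_mg,
            "inhaled_dose_literature_mg": lit_plan.inhaled_dose_mg,
        })
    dose_plans = pd.DataFrame(plan_rows).set_index("api")

    ratio_rows, capsule_rows = [], []
    for a, b in PAIRS:
        if a not in compounds or b not in compounds:
            continue
        pa, pb = compounds[a], compounds[b]
        for source in ("model", "literature"):
            ratio = dosing.molar_ratio(
                plans[(a, source)].inhaled_dose_mg, pa.mw_salt,
                plans[(b, source)].inhaled_dose_mg, pb.mw_salt,
                api_a=a, api_b=b,
            )
            ratio_rows.append({
                "pair": f"{a}-{b}", "source": source,
                "ratio_b_per_a": ratio.ratio_b_per_a,
                "formatted": ratio.formatted(),
            })
            cap = dosing.capsule_composition(config.capsule_fill_mg,
                                             ratio.ratio_b_per_a, pa.mw_salt, pb.mw_salt)
            capsule_rows.append({
                "pair": f"{a}-{b}", "source": source,
                "fill_mass_mg": cap.fill_mass_mg,
                f"mass_a_mg": cap.mass_a_mg, f"mass_b_mg": cap.mass_b_mg,
            })
    molar_ratios = pd.DataFrame(ratio_rows)
    capsules = pd.DataFrame(capsule_rows)

    report = DoseTranslationReport(
        profiles=profiles, pk_table=pk_table, validation=validation,
        dose_plans=dose_plans, molar_ratios=molar_ratios, capsules=capsules,
        lung_exposure_percent=exposures, kp_scales=kp_scales,
    )
    if config.output_dir:
        _write_dose_outputs(report, Path(config.output_dir))
    return report


def _write_dose_outputs(report: DoseTranslationReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for api, prof in report.profiles.items():
        prof.to_csv(outdir / f"profile_{api.lower()}.csv")
    report.pk_table.to_csv(outdir / "pk_table.csv")
    report.validation.table.to_csv(outdir / "validation.csv", index=False)
    (outdir / "validation.txt").write_text(report.validation.to_text() + "\n")
    report.dose_plans.to_csv(outdir / "dose_plans.csv")
    report.molar_ratios.to_csv(outdir / "molar_ratios.csv", index=False)
    report.capsules.to_csv(outdir / "capsules.csv", index=False)
    (outdir / "lung_exposure.json").write_text(
        json.dumps({k: round(v, 6) for k, v in report.lung_exposure_percent.items()},
                   indent=2, sort_keys=True) + "\n"
    )


def run_formulation_report(
    impactor_csvs: Sequence = (),
    psd_csvs: Sequence = (),
    dissolution_csvs: Sequence[tuple] = (),  # (path, dose_ug) pairs
    output_dir: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Aerosol/PSD/dissolution summaries in the layout of the study tables."""
    out: dict[str, pd.DataFrame] = {}

    rows = []
    for path in impactor_csvs:
        df = pd.read_csv(path)
        if df.empty:
            raise aerosol.InputError(f"{path}: empty impactor CSV")
        for api in sorted(df["api"].unique()):
            run = aerosol.impactor_run_from_csv(path, api=api)
            m = aerosol.aerosol_metrics(run)
            rows.append({"file": str(path), "api": api, "ef_percent": m.ef_percent,
                         "fpm_mg": m.fpm_mg, "fpf_percent": m.fpf_percent,
                         "emitted_dose_mg": m.emitted_dose_mg})
    if rows:
        out["aerosol"] = pd.DataFrame(rows)

    rows = []
    for path in psd_csvs:
        s = aerosol.psd_from_csv(path)
        rows.append({"file": str(path), "x10_um": s.x10_um, "x50_um": s.x50_um,
                     "x90_um": s.x90_um, "span": s.span, "smd_um": s.smd_um,
                     "frac_below_5um_percent": s.frac_below_5um_percent})
    if rows:
        out["psd"] = pd.DataFrame(rows)

    frames = []
    for path, dose_ug in dissolution_csvs:
        run = aerosol.dissolution_run_from_csv(path, dose_ug=dose_ug)
        prof = aerosol.dissolution_profile(run)
        prof.insert(0, "file", str(path))
        frames.append(prof)
    if frames:
        out["dissolution"] = pd.concat(frames, ignore_index=True)

    if output_dir:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"{name}_report.csv", index=False)
    return out
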