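import numpy as np
import pytest

from tbinhale.compounds import ParameterError, load_compound
from tbinhale.nca import nca
from tbinhale.pbpk import (
    AbsorptionModel,
    absorption_from_peff,
    check_mass_balance,
    hepatic_availability,
    profile_from_csv,
    reconstructed_vss,
    rescale_kp_to_vdss,
    simulate,
)
from tbinhale.physiology import TISSUES, build_physiology, study_subject
from tbinhale.synth import one_compartment_oral


class TestKpRescaling:
    def test_identity_when_vss_already_closed(self):
        params = load_compound("ETH")
        phys = build_physiology(study_subject("ETH"))
        once = rescale_kp_to_vdss(params, phys)
        twice = rescale_kp_to_vdss(once, phys)
        assert twice.kp_scale == pytest.approx(1.0, rel=1e-12)
        for t in TISSUES:
            assert twice.kp[t] == pytest.approx(once.kp[t], rel=1e-12)

    def test_doubled_kp_recovers_half_scale(self):
        params = load_compound("MOX")
        phys = build_physiology(study_subject("MOX"))
        base = rescale_kp_to_vdss(params, phys)
        doubled = params.with_kp({t: 2 * v for t, v in params.kp.items()}, 1.0)
        rescaled = rescale_kp_to_vdss(doubled, phys)
        assert rescaled.kp_scale == pytest.approx(base.kp_scale / 2, rel=1e-12)
        for t in TISSUES:
            assert rescaled.kp[t] == pytest.approx(base.kp[t], rel=1e-12)

    def test_eth_vss_closes_to_target(self):
        # Vdss 6.1 L/kg at 79.3 kg body weight -> 483.73 L reconstructed
        params = load_compound("ETH")
        phys = build_physiology(study_subject("ETH"))
        scaled = rescale_kp_to_vdss(params, phys)
        assert reconstructed_vss(scaled, phys) == pytest.approx(483.73, rel=1e-6)

    def test_vdss_below_plasma_volume_rejected(self):
        from dataclasses import replace
        params = replace(load_compound("RIF"), vdss_L_per_kg=0.01)
        phys = build_physiology(study_subject("RIF"))
        with pytest.raises(ParameterError, match="plasma volume"):
            rescale_kp_to_vdss(params, phys)


class TestAbsorptionModel:
    def test_rif_permeability_conversion_frozen(self):
        # ka = 2 * 1.3e-4 cm/s / 1.25 cm * 3600 s/h, 7-segment chain
        model = absorption_from_peff(1.3)
        assert model.ka_per_h == pytest.approx(0.74880, abs=1e-5)
        assert model.n_transit == 7
        assert model.fraction_absorbed == pytest.approx(0.88085, abs=2e-5)

    def test_limits_of_absorbed_fraction(self):
        assert absorption_from_peff(1e-9).fraction_absorbed < 1e-6
        assert absorption_from_peff(1e4).fraction_absorbed > 0.999999
        with pytest.raises(ParameterError):
            absorption_from_peff(0.0)

    def test_transit_chain_fraction_matches_simulated_gut_loss(self):
        # the closed form 1-(1+ka T/n)^-n must equal what the ODE loses
        params = load_compound("RIF")
        phys = build_physiology(study_subject("RIF"))
        scaled = rescale_kp_to_vdss(params, phys)
        absorption = absorption_from_peff(params.peff_1e4_cm_per_s)
        prof = simulate(scaled, phys, absorption)
        absorbed = prof.amounts_balance["absorbed_ug"].iloc[-1]
        assert absorbed / prof.dose_ug == pytest.approx(
            absorption.fraction_absorbed, rel=1e-4)


@pytest.fixture(scope="module")
def rif_context():
    params = load_compound("RIF")
    phys = build_physiology(study_subject("RIF"))
    scaled = rescale_kp_to_vdss(params, phys)
    absorption = absorption_from_peff(params.peff_1e4_cm_per_s)
    return scaled, phys, absorption


class TestSimulate:
    def test_zero_dose_gives_zero_profile(self, rif_context):
        scaled, phys, absorption = rif_context
        prof = simulate(scaled, phys, absorption, dose_mg=0.0)
        assert np.all(prof.plasma_ug_per_mL == 0.0)
        assert all(np.all(c == 0.0) for c in prof.tissue_ug_per_mL.values())

    def test_mass_balance_within_tenth_percent(self, rif_context):
        scaled, phys, absorption = rif_context
        prof = simulate(scaled, phys, absorption)
        assert check_mass_balance(prof, rel_tol=1e-3) < 1e-3

    def test_dose_linearity(self, rif_context):
        scaled, phys, absorption = rif_context
        p1 = simulate(scaled, phys, absorption, dose_mg=300.0)
        p2 = simulate(scaled, phys, absorption, dose_mg=600.0)
        ref = p1.plasma_ug_per_mL.max()
        assert np.allclose(p2.plasma_ug_per_mL, 2 * p1.plasma_ug_per_mL,
                           atol=1e-6 * ref)

    def test_plasma_auc_matches_dose_over_clearance(self, rif_context):
        # linear system identity: AUC0-inf = Fa*Fh*Dose/CL
        scaled, phys, absorption = rif_context
        prof = simulate(scaled, phys, absorption)
        res = nca(prof.times_h, prof.plasma_ug_per_mL)
        f_sys = absorption.fraction_absorbed * hepatic_availability(scaled, phys)
        expected = f_sys * prof.dose_ug / scaled.cl_iv_L_per_h / 1000.0
        assert res.auc_0_inf == pytest.approx(expected, rel=0.01)

    def test_tissue_to_plasma_auc_ratio_equals_kp(self, rif_context):
        scaled, phys, absorption = rif_context
        prof = simulate(scaled, phys, absorption)
        auc_p = nca(prof.times_h, prof.plasma_ug_per_mL).auc_0_inf
        for tissue in ("Lung", "Muscle", "Adipose", "RestOfBody"):
            auc_t = nca(prof.times_h, prof.tissue_ug_per_mL[tissue]).auc_0_inf
            assert auc_t / auc_p == pytest.approx(scaled.kp[tissue], rel=0.01)

    def test_profile_csv_round_trip(self, rif_context, tmp_path):
        scaled, phys, absorption = rif_context
        prof = simulate(scaled, phys, absorption)
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        back = profile_from_csv(path, dose_ug=prof.dose_ug, api="RIF")
        assert np.allclose(back.plasma_ug_per_mL, prof.plasma_ug_per_mL)
        assert np.allclose(back.tissue_ug_per_mL["Lung"], prof.tissue_ug_per_mL["Lung"])

    def test_short_horizon_rejected(self, rif_context):
        scaled, phys, absorption = rif_context
        with pytest.raises(ValueError, match="24"):
            simulate(scaled, phys, absorption, horizon_h=12.0)


class TestOneCompartmentLimit:
    def test_reduces_to_bateman_with_degenerate_physiology(self):
        """With all Kp = 1, bp = 1, renal-only elimination and vanishing
        tissue volumes, the whole-body model collapses to a one-compartment
        oral model (the reduction holds in the fast-perfusion limit, with
        clearance small against cardiac output); plasma must match the
        Bateman closed form."""
        from dataclasses import replace

        from tbinhale.physiology import PhysiologyTable

        v_ven, v_art = 30.0, 1e-3
        tiny = 1e-4
        vols = {t: tiny for t in TISSUES}
        flows_frac = {t: 1.0 / 12.0 for t in TISSUES if t != "Lung"}
        co = 5000.0
        phys = PhysiologyTable(
            body_weight_kg=70.0,
            tissue_volumes=vols,
            blood_flows={**{t: co * f for t, f in flows_frac.items()}, "Lung": co},
            cardiac_output_L_per_h=co,
            venous_blood_L=v_ven, arterial_blood_L=v_art, hematocrit=0.0,
            portal_inflow_tissues=frozenset({"Spleen"}),
        )
        cl = 5.0
        params = replace(
            load_compound("RIF"), bp_ratio=1.0, fu=1.0,
            cl_iv_L_per_h=cl, cl_r_L_per_h=cl,  # no hepatic extraction
            kp={t: 1.0 for t in TISSUES},
        )
        ka = 0.8
        absorption = AbsorptionModel(ka_per_h=ka, n_transit=1, transit_time_h=1e9)
        prof = simulate(params, phys, absorption, horizon_h=48.0)
        v_total = v_ven + v_art + sum(vols.values())
        expected = one_compartment_oral(prof.times_h, prof.dose_ug / 1000.0,
                                        ka, cl, v_total) / 1.0
        sup = np.max(np.abs(prof.plasma_ug_per_mL - expected))
        assert sup <= 0.005 * expected.max()
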