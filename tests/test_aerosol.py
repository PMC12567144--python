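import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbinhale.aerosol import (
    DissolutionRun,
    ImpactorRun,
    InputError,
    aerosol_metrics,
    content_uniformity,
    dissolution_profile,
    psd_summary,
    span_from_quantiles,
)


class TestAerosolMetrics:
    def test_constructed_run_arithmetic(self):
        # stages 7.5/5/5/12.5 mg: recovered 30, EF 75 %, emitted 22.5,
        # FPF 55.6 %, FPM 12.5 mg
        run = ImpactorRun(7500.0, 5000.0, 5000.0, 12500.0)
        m = aerosol_metrics(run)
        assert m.recovered_dose_mg == pytest.approx(30.0)
        assert m.ef_percent == pytest.approx(75.0)
        assert m.emitted_dose_mg == pytest.approx(22.5)
        assert m.fpm_mg == pytest.approx(12.5)
        assert m.fpf_percent == pytest.approx(55.556, abs=0.001)

    def test_all_mass_in_device(self):
        run = ImpactorRun(25000.0, 0.0, 0.0, 0.0)
        with pytest.warns(UserWarning, match="emitted"):
            m = aerosol_metrics(run)
        assert m.ef_percent == 0.0
        assert m.fpf_percent == 0.0

    def test_filter_only_deposition(self):
        m = aerosol_metrics(ImpactorRun(0.0, 0.0, 0.0, 20000.0))
        assert m.ef_percent == 100.0
        assert m.fpf_percent == 100.0

    def test_negative_stage_mass_rejected(self):
        with pytest.raises(InputError):
            ImpactorRun(-1.0, 5000.0, 5000.0, 12500.0)

    def test_empty_run_rejected(self):
        with pytest.raises(InputError, match="recovered"):
            ImpactorRun(0.0, 0.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e5), min_size=4, max_size=4))
    def test_bounds_for_arbitrary_stage_masses(self, masses):
        if sum(masses) <= 0:
            return
        run = ImpactorRun(*masses)
        emitted = run.recovered_ug - run.inhaler_capsule_ug
        if emitted <= 0 and run.filter_ug > 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = aerosol_metrics(run)
        eps = 1e-9
        assert 0.0 <= m.ef_percent <= 100.0 + eps
        assert 0.0 <= m.fpf_percent <= 100.0 + eps
        assert m.fpm_mg <= m.emitted_dose_mg + 1e-12 or m.emitted_dose_mg == 0


class TestContentUniformity:
    def test_identical_samples(self):
        res = content_uniformity([95.7] * 10)
        assert res.rsd_percent == pytest.approx(0.0, abs=1e-9)
        assert res.uniformity_pass and res.homogeneity_pass

    def test_heterogeneous_mixture_fails_homogeneity(self):
        # mean ~92.8 %, RSD ~11.8 %: uniform in mean but not homogeneous
        rng = np.random.default_rng(42)
        samples = 92.8 * (1 + 0.118 * rng.standard_normal(10))
        samples *= 92.8 / samples.mean()
        res = content_uniformity(samples)
        assert res.uniformity_pass
        assert res.rsd_percent > 5.0
        assert not res.homogeneity_pass

    def test_low_mean_fails_uniformity(self):
        res = content_uniformity([83.0, 83.1, 82.9, 83.0])
        assert not res.uniformity_pass
        assert res.homogeneity_pass

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            content_uniformity([100.0])


class TestPSDSummary:
    def test_span_from_published_quantiles(self):
        assert span_from_quantiles(1.30, 3.77, 7.23) == pytest.approx(1.57, abs=0.005)

    def test_monodisperse(self):
        s = psd_summary([3.0, 3.0], [1.0])
        assert s.x10_um == s.x50_um == s.x90_um == 3.0
        assert s.span == 0.0
        assert s.smd_um == pytest.approx(3.0)
        assert s.frac_below_5um_percent == 100.0

    def test_sauter_mean_is_harmonic(self):
        # two equal-mass populations at 2 and 4 µm -> SMD 2.67 µm
        s = psd_summary([2.0, 2.0, 4.0, 4.0], [0.5, 0.0, 0.5])
        assert s.smd_um == pytest.approx(1.0 / (0.5 / 2 + 0.5 / 4), rel=1e-12)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(InputError, match="sorted"):
            psd_summary([1.0, 0.5, 2.0], [0.5, 0.5])

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InputError, match="sum"):
            psd_summary([1.0, 2.0, 3.0], [0.5, 0.4])

    @settings(max_examples=40, deadline=None)
    @given(scale=st.floats(0.1, 10.0))
    def test_quantiles_order_preserving_under_rescaling(self, scale):
        edges = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        frac = np.array([0.1, 0.3, 0.4, 0.2])
        base = psd_summary(edges, frac)
        scaled = psd_summary(edges * scale, frac)
        assert scaled.x10_um == pytest.approx(base.x10_um * scale, rel=1e-9)
        assert scaled.x50_um == pytest.approx(base.x50_um * scale, rel=1e-9)
        assert scaled.x90_um == pytest.approx(base.x90_um * scale, rel=1e-9)
        assert scaled.span == pytest.approx(base.span, rel=1e-9)


class TestDissolution:
    def test_no_withdrawal_reduces_to_concentration_scaling(self):
        run = DissolutionRun(np.array([0.0, 5.0, 10.0]),
                             np.array([10.0, 20.0, 40.0]),
                             dose_ug=4000.0, vessel_volume_mL=55.0,
                             sample_volume_mL=0.0)
        prof = dissolution_profile(run)
        expected = np.array([10.0, 20.0, 40.0]) * 55.0 / 4000.0 * 100.0
        assert np.allclose(prof["percent_dissolved"], expected)

    def test_correction_direction_with_constant_concentration(self):
        # constant C = dose/V: each replacement removes drug, so the
        # corrected cumulative exceeds 100 % by the replaced fraction
        v_ml, dose = 55.0, 5500.0
        c = dose / v_ml
        run = DissolutionRun(np.array([0.0, 5.0, 10.0]), np.array([c, c, c]),
                             dose_ug=dose, vessel_volume_mL=v_ml,
                             sample_volume_mL=1.0)
        prof = dissolution_profile(run)
        expected = 100.0 * np.array([1.0, 1.0 + c / dose, 1.0 + 2 * c / dose])
        assert np.allclose(prof["percent_dissolved"], expected)

    def test_declining_series_warns_not_fails(self):
        run = DissolutionRun(np.array([0.0, 5.0, 10.0]),
                             np.array([50.0, 40.0, 30.0]),
                             dose_ug=4000.0, sample_volume_mL=1.0)
        with pytest.warns(UserWarning, match="monotone"):
            prof = dissolution_profile(run)
        assert len(prof) == 3

    def test_zero_dose_rejected(self):
        run = DissolutionRun(np.array([0.0, 5.0]), np.array([1.0, 2.0]),
                             dose_ug=0.0)
        with pytest.raises(InputError):
            dissolution_profile(run)

    def test_sample_volume_exceeding_vessel_rejected(self):
        with pytest.raises(InputError):
            DissolutionRun(np.array([0.0, 5.0]), np.array([1.0, 2.0]),
                           dose_ug=100.0, vessel_volume_mL=1.0,
                           sample_volume_mL=2.0)
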