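"""Comparison statistics, rRMSD, dose-rate budget, TPR20,10."""

import numpy as np
import pytest

import linacspec as ls


def binned(values, lower=0.0, width=0.2, **kwargs):
    grid = ls.EnergyGrid(lower=lower, width=width, n_bins=len(values))
    return ls.BinnedSpectrum(grid=grid, values=np.asarray(values, float), **kwargs)


class TestCompareSpectra:
    def test_identical_spectra_are_not_significant(self):
        s = binned([1, 5, 9, 4, 2, 1])
        rep = ls.compare_spectra_tests(s, s)
        assert rep.ks_statistic == 0.0
        assert not rep.any_significant
        assert rep.p_chi2 == pytest.approx(1.0)

    def test_disjoint_support_detected_by_ks(self):
        s1 = binned([10, 10, 10, 0, 0, 0])
        s2 = binned([0, 0, 0, 10, 10, 10])
        rep = ls.compare_spectra_tests(s1, s2)
        assert rep.ks_statistic == pytest.approx(1.0)
        assert rep.p_ks < 0.05

    def test_two_sample_tests_are_symmetric(self):
        s1 = binned([5, 9, 3, 1, 0, 2])
        s2 = binned([4, 7, 6, 2, 1, 1])
        a = ls.compare_spectra_tests(s1, s2)
        b = ls.compare_spectra_tests(s2, s1)
        assert a.p_ranksum == pytest.approx(b.p_ranksum)
        assert a.p_chi2 == pytest.approx(b.p_chi2)
        assert a.p_ks == pytest.approx(b.p_ks)

    def test_scale_invariance(self):
        s1 = binned([5, 9, 3, 1, 0, 2])
        s2 = binned([50, 90, 30, 10, 0, 20])
        rep = ls.compare_spectra_tests(s1, s2)
        assert not rep.any_significant
        assert rep.ks_statistic == pytest.approx(0.0, abs=1e-12)

    def test_grid_mismatch_and_empty_rejected(self):
        s1 = binned([1, 2, 3])
        with pytest.raises(ls.ValidationError):
            ls.compare_spectra_tests(s1, binned([1, 2, 3], width=0.5))
        with pytest.raises(ls.ValidationError):
            ls.compare_spectra_tests(s1, binned([0, 0, 0]))


class TestRRMSD:
    def test_identical_curves_give_zero(self):
        c = ls.PDDCurve(depths=np.array([1.0, 5.0, 10.0]),
                        values=np.array([100.0, 80.0, 60.0]))
        assert ls.rrmsd(c, c) == pytest.approx(0.0)

    def test_uniform_one_percent_offset(self):
        meas = ls.PDDCurve(depths=np.array([1.0, 5.0, 10.0]),
                           values=np.array([100.0, 80.0, 60.0]))
        calc = ls.PDDCurve(depths=meas.depths, values=meas.values * 1.01)
        assert ls.rrmsd(calc, meas) == pytest.approx(1.0, rel=1e-9)

    def test_two_point_toy_curves(self):
        meas = ls.PDDCurve(depths=np.array([1.0, 2.0]),
                           values=np.array([100.0, 50.0]))
        calc = ls.PDDCurve(depths=meas.depths,
                           values=np.array([100.0, 51.0]))
        assert ls.rrmsd(calc, meas) == pytest.approx(1.414, abs=2e-3)

    def test_invariant_under_common_rescaling(self):
        meas = ls.PDDCurve(depths=np.array([1.0, 5.0, 10.0]),
                           values=np.array([100.0, 80.0, 60.0]))
        calc = ls.PDDCurve(depths=meas.depths,
                           values=np.array([99.0, 81.0, 61.0]))
        scaled = ls.rrmsd(
            ls.PDDCurve(depths=calc.depths, values=calc.values * 3.0),
            ls.PDDCurve(depths=meas.depths, values=meas.values * 3.0))
        assert scaled == pytest.approx(ls.rrmsd(calc, meas))

    def test_calc_interpolated_to_measured_depths(self):
        calc = ls.PDDCurve(depths=np.array([0.0, 10.0]),
                           values=np.array([100.0, 50.0]))
        meas = ls.PDDCurve(depths=np.array([2.0, 4.0, 6.0]),
                           values=np.array([90.0, 80.0, 70.0]))
        assert ls.rrmsd(calc, meas) == pytest.approx(0.0, abs=1e-9)

    def test_non_positive_pdd_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.PDDCurve(depths=np.array([1.0, 2.0]), values=np.array([100.0, 0.0]))


class TestDoseRateBudget:
    def test_monoenergetic_1_mev_hand_value(self):
        """1 photon/cm^2/pulse at 180 pulse/s: D = 180 * 1 MeV *
        mu_en/rho(1 MeV) * 1.602e-10, about 0.89 nGy/s."""
        grid = ls.EnergyGrid(lower=0.1, width=0.2, n_bins=5)
        spectrum = ls.BinnedSpectrum(grid=grid, values=[0, 0, 0, 0, 1.0],
                                     normalized=True)  # center 1.0 MeV
        rate = ls.plan_dose_rate(spectrum, ls.LinacPulseConfig())
        assert rate == pytest.approx(8.9e-10, rel=0.02)

    def test_linearity_in_pulse_rate_and_fluence(self):
        spectrum = ls.generate_true_spectrum()
        base = ls.plan_dose_rate(spectrum, ls.LinacPulseConfig(180.0, 1.0))
        assert ls.plan_dose_rate(
            spectrum, ls.LinacPulseConfig(360.0, 1.0)) == pytest.approx(2 * base)
        assert ls.plan_dose_rate(
            spectrum, ls.LinacPulseConfig(180.0, 5.0)) == pytest.approx(5 * base)
        assert ls.plan_dose_rate(
            spectrum, ls.LinacPulseConfig(180.0, 0.0)) == 0.0

    def test_inverse_budget_round_trips(self):
        spectrum = ls.generate_true_spectrum()
        config = ls.LinacPulseConfig(180.0, 1.0)
        target = 3.1e-9
        phi = ls.fluence_rate_for_dose_rate(spectrum, config, target)
        forward = ls.plan_dose_rate(
            spectrum, ls.LinacPulseConfig(180.0, phi))
        assert forward == pytest.approx(target, rel=1e-9)

    def test_unnormalized_spectrum_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.plan_dose_rate(binned([1.0, 2.0]), ls.LinacPulseConfig())


class TestTPR:
    def test_ratio_of_readings(self):
        assert ls.tpr_20_10(ls.TPRMeasurement(m20=0.665, m10=1.0)) == \
            pytest.approx(0.665)

    def test_equal_readings_give_unity(self):
        assert ls.tpr_20_10(ls.TPRMeasurement(m20=2.5, m10=2.5)) == 1.0

    def test_consistency_helper_at_stated_tolerance(self):
        """Normal- and low-dose-rate beam quality agree within one SD."""
        assert ls.tpr_consistent(0.665, 0.667, tolerance=0.004)
        assert not ls.tpr_consistent(0.665, 0.672, tolerance=0.004)

    def test_non_positive_readings_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.TPRMeasurement(m20=0.0, m10=1.0)
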