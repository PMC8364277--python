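"""Response matrix assembly, Gaussian broadening, efficiencies, peak areas."""

import numpy as np
import pytest

import linacspec as ls
from linacspec.response import peak_area


def measure_fwhm(centers, values):
    """Full width at half maximum by linear interpolation of the crossings."""
    peak = values.argmax()
    half = values[peak] / 2.0
    left = np.interp(half, values[: peak + 1], centers[: peak + 1])
    right = np.interp(half, values[peak:][::-1], centers[peak:][::-1])
    return right - left


def delta_response(center_energy, width=0.004, upper=2.0):
    """Single-column response with unit mass at the bin containing
    ``center_energy`` on a fine deposited grid."""
    grid = ls.EnergyGrid(lower=0.0, width=width, n_bins=int(round(upper / width)))
    i = grid.index_of(center_energy)
    matrix = np.zeros((grid.n_bins, 1))
    matrix[i, 0] = 1.0
    incident = ls.EnergyGrid(lower=0.0, width=upper, n_bins=1)
    return ls.ResponseMatrix(matrix=matrix, incident_grid=incident,
                             deposited_grid=grid,
                             histories_per_column=np.array([1])), grid


class TestBroadening:
    def test_unit_mass_at_cs137_line_gets_11p7_percent_fwhm(self):
        """K=9.53 implies FWHM = 9.53*sqrt(0.662)/100 = 0.0775 MeV at the
        137Cs energy."""
        resp, grid = delta_response(0.662)
        broad = ls.broaden_response(resp, ls.ResolutionModel(K=9.53))
        fwhm = measure_fwhm(grid.centers, broad.matrix[:, 0])
        assert fwhm == pytest.approx(0.0775, rel=0.01)

    def test_zero_k_leaves_response_unchanged(self):
        resp, _ = delta_response(1.0)
        broad = ls.broaden_response(resp, ls.ResolutionModel(K=0.0))
        np.testing.assert_array_equal(broad.matrix, resp.matrix)
        assert broad.broadened

    def test_double_broadening_rejected(self):
        resp, _ = delta_response(1.0)
        broad = ls.broaden_response(resp, ls.ResolutionModel())
        with pytest.raises(ls.ValidationError, match="already broadened"):
            ls.broaden_response(broad, ls.ResolutionModel())

    def test_mass_conserved_for_interior_peaks(self):
        resp, _ = delta_response(1.0, upper=2.0)  # >3 FWHM from both edges
        broad = ls.broaden_response(resp, ls.ResolutionModel(K=9.53))
        assert abs(broad.matrix[:, 0].sum() - 1.0) < 1e-3

    def test_unbroadened_response_has_no_mass_above_incident_bin(self, pencil_response):
        m = pencil_response.matrix
        for j in range(pencil_response.incident_grid.n_bins):
            assert np.all(m[j + 1:, j] == 0)

    def test_column_sums_are_probabilities(self, pencil_response, broadened_response):
        for resp in (pencil_response, broadened_response):
            sums = resp.total_efficiency
            assert np.all(sums >= 0)
            assert np.all(sums <= 1 + 1e-9)


class TestResolutionFit:
    def test_single_point_inversion_recovers_k(self):
        model = ls.fit_resolution_constant([(0.662, 0.0775)])
        assert model.K == pytest.approx(9.53, rel=5e-3)

    def test_broaden_measure_fit_round_trip(self):
        """Broadening three calibration deltas and refitting recovers K
        within 1%."""
        peaks = []
        for energy in (0.662, 1.174, 1.330):  # 137Cs and 60Co bin centers
            resp, grid = delta_response(energy)
            broad = ls.broaden_response(resp, ls.ResolutionModel(K=9.53))
            peaks.append((energy, measure_fwhm(grid.centers, broad.matrix[:, 0])))
        fitted = ls.fit_resolution_constant(peaks)
        assert fitted.K == pytest.approx(9.53, rel=0.01)

    def test_resolution_model_shape(self):
        model = ls.ResolutionModel(K=9.53)
        assert model.resolution_percent(0.662) == pytest.approx(11.71, rel=1e-3)
        energies = np.linspace(0.2, 8.0, 50)
        assert np.all(np.diff(model.resolution_percent(energies)) < 0)

    def test_empty_peak_list_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.fit_resolution_constant([])


class TestPeakArea:
    def test_triangle_peak_on_flat_background(self):
        assert peak_area([2, 10, 20, 10, 2], (0, 4)) == pytest.approx(34.0)

    def test_flat_spectrum_nets_zero(self):
        assert peak_area([7.0] * 6, (0, 5)) == pytest.approx(0.0)

    def test_gaussian_on_linear_ramp_recovers_area(self):
        centers = np.arange(100) * 0.01 + 0.005
        sigma, area = 0.05, 1000.0
        values = 50 + 100 * centers
        values = values + area / (sigma * np.sqrt(2 * np.pi)) * 0.01 * np.exp(
            -0.5 * ((centers - 0.5) / sigma) ** 2)
        lo, hi = 35, 64  # +-3 sigma around the peak
        assert peak_area(values, (lo, hi)) == pytest.approx(area, rel=0.05)

    def test_invalid_windows_rejected(self):
        with pytest.raises(ls.ValidationError):
            peak_area([1, 2, 3], (0, 1))
        with pytest.raises(ls.ValidationError):
            peak_area([1, 2, 3], (0, 5))


class TestEfficiency:
    def test_ratio_arithmetic(self):
        eff = ls.photopeak_efficiency([0, 52, 0], (0, 2), c_i=100.0)
        assert eff.eps_p == pytest.approx(0.52)
        assert eff.eps_tot == pytest.approx(0.52)

    def test_zero_incident_count_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.photopeak_efficiency([1, 2, 1], (0, 2), c_i=0.0)

    def test_simulation_efficiencies_ordered(self, run_1mev_broad):
        eff = ls.efficiency_from_simulation(run_1mev_broad)
        assert 0 < eff.eps_p <= eff.eps_tot <= 1
        assert eff.se_p > 0 and eff.se_tot > 0

    def test_inconsistent_result_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.EfficiencyResult(energy=1.0, eps_p=0.9, eps_tot=0.5,
                                c_p=90, c_i=100)

    def test_peak_area_estimator_agrees_with_full_energy_tally(
            self, crystal, pencil_beam):
        """The 137Cs photopeak efficiency measured from the broadened
        spectrum (net peak area over a +-3 sigma window) tracks the
        unbroadened full-energy tally to within a few percent."""
        n = 100_000
        grid = ls.EnergyGrid(lower=0.0, width=0.02, n_bins=40)
        run = ls.simulate_depositions(crystal, pencil_beam, 0.662, n,
                                      seed=31, grid=grid)
        ep_tally = run.full_energy_count(window=0.2) / n
        incident = ls.EnergyGrid(lower=0.0, width=0.8, n_bins=1)
        resp = ls.ResponseMatrix(matrix=run.histogram[:, None] / n,
                                 incident_grid=incident, deposited_grid=grid,
                                 histories_per_column=np.array([n]))
        broad = ls.broaden_response(resp, ls.ResolutionModel(K=9.53))
        sigma = ls.ResolutionModel().sigma(0.662)
        window = (grid.index_of(0.662 - 3 * sigma),
                  grid.index_of(0.662 + 3 * sigma))
        eff = ls.photopeak_efficiency(broad.matrix[:, 0] * n, window,
                                      c_i=n, energy=0.662)
        assert eff.eps_p == pytest.approx(ep_tally, rel=0.05)


class TestSerialization:
    def test_round_trip_preserves_matrix_and_grids(self, tmp_path, pencil_response):
        path = tmp_path / "response.tsv"
        ls.write_response(pencil_response, path)
        back = ls.read_response(path)
        np.testing.assert_allclose(back.matrix, pencil_response.matrix, rtol=1e-6)
        assert back.incident_grid == pencil_response.incident_grid
        assert back.deposited_grid == pencil_response.deposited_grid
        assert back.broadened == pencil_response.broadened
        np.testing.assert_array_equal(back.histories_per_column,
                                      pencil_response.histories_per_column)

    def test_broadened_flag_round_trips(self, tmp_path, broadened_response):
        path = tmp_path / "broad.tsv"
        ls.write_response(broadened_response, path)
        assert ls.read_response(path).broadened


def test_build_response_matrix_columns_match_single_runs(crystal, pencil_beam):
    """Each column is the normalized deposition histogram at the bin-center
    energy, built from a deterministic per-column seed."""
    grid = ls.EnergyGrid(lower=0.0, width=0.2, n_bins=5)
    resp = ls.build_response_matrix(crystal, pencil_beam, grid=grid,
                                    n_histories_per_column=2000, seed=3)
    col_seeds = np.random.SeedSequence(3).generate_state(grid.n_bins)
    redo = ls.simulate_depositions(crystal, pencil_beam, float(grid.centers[2]),
                                   2000, int(col_seeds[2]), grid=grid)
    np.testing.assert_allclose(resp.matrix[:, 2], redo.histogram / 2000)
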