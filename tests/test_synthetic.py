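"""Synthetic 6 MV truth spectrum, forward model, and counting noise."""

import numpy as np
import pytest

import linacspec as ls


class TestTruthSpectrum:
    def test_default_6mv_mode_is_the_half_mev_bin(self):
        truth = ls.generate_true_spectrum()
        mode_center = truth.grid.centers[np.argmax(truth.values)]
        assert mode_center == pytest.approx(0.5)

    def test_default_6mv_mean_energy(self):
        truth = ls.generate_true_spectrum()
        assert ls.mean_energy(truth) == pytest.approx(1.7, abs=0.05)

    def test_normalized_and_zero_above_endpoint(self):
        truth = ls.generate_true_spectrum()
        assert truth.total == pytest.approx(1.0, abs=1e-9)
        assert np.all(truth.values[truth.grid.edges[:-1] >= 6.0] == 0)

    def test_density_vanishes_at_and_beyond_endpoint(self):
        params = ls.BremsstrahlungParams()
        assert params.density(np.array([6.0, 6.5, 10.0])).max() == 0.0
        assert np.all(params.density(np.linspace(0.01, 5.99, 100)) > 0)

    def test_grid_must_reach_endpoint(self):
        small = ls.EnergyGrid(lower=0.0, width=0.2, n_bins=10)
        with pytest.raises(ls.ValidationError):
            ls.generate_true_spectrum(grid=small)

    def test_invalid_params_rejected(self):
        with pytest.raises(ls.ValidationError):
            ls.BremsstrahlungParams(e_max=-1.0)


class TestForwardFold:
    def test_identity_response_scales_truth(self):
        grid = ls.EnergyGrid(lower=0.0, width=1.0, n_bins=8)
        resp = ls.ResponseMatrix(matrix=np.eye(8), incident_grid=grid,
                                 deposited_grid=grid,
                                 histories_per_column=np.ones(8, int))
        truth = ls.BinnedSpectrum(grid=grid, values=np.arange(8.0) + 1).normalize()
        folded = ls.forward_fold(truth, resp, 1000.0)
        np.testing.assert_allclose(folded.values, 1000.0 * truth.values)

    def test_total_counts_follow_column_sum_identity(self, broadened_response):
        truth = ls.generate_true_spectrum()
        folded = ls.forward_fold(truth, broadened_response, 1e6)
        expected_total = 1e6 * float(
            broadened_response.total_efficiency @ truth.values)
        assert folded.total == pytest.approx(expected_total, rel=1e-9)

    def test_folding_shifts_mean_down(self, broadened_response):
        """The Compton continuum moves counts below the incident energy."""
        truth = ls.generate_true_spectrum()
        folded = ls.forward_fold(truth, broadened_response, 1e6)
        assert ls.mean_energy(folded) < ls.mean_energy(truth)

    def test_grid_mismatch_rejected(self, broadened_response):
        bad = ls.BinnedSpectrum(grid=ls.EnergyGrid(lower=0.0, width=0.5, n_bins=16),
                                values=np.ones(16) / 16, normalized=True)
        with pytest.raises(ls.ValidationError):
            ls.forward_fold(bad, broadened_response, 100.0)


class TestSampling:
    def test_zero_expectation_draws_zero(self):
        grid = ls.EnergyGrid(lower=0.0, width=1.0, n_bins=4)
        zero = ls.BinnedSpectrum(grid=grid, values=np.zeros(4))
        assert ls.sample_counts(zero, seed=1).total == 0

    def test_same_seed_same_draw(self):
        grid = ls.EnergyGrid(lower=0.0, width=1.0, n_bins=6)
        expected = ls.BinnedSpectrum(grid=grid, values=np.full(6, 50.0))
        a = ls.sample_counts(expected, seed=3)
        b = ls.sample_counts(expected, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values,
                                  ls.sample_counts(expected, seed=4).values)

    def test_seed_averaged_draws_match_expectation(self):
        grid = ls.EnergyGrid(lower=0.0, width=1.0, n_bins=3)
        mu = np.array([20.0, 200.0, 2000.0])
        expected = ls.BinnedSpectrum(grid=grid, values=mu)
        n_rep = 500
        draws = np.array([ls.sample_counts(expected, seed=s).values
                          for s in range(n_rep)])
        se = np.sqrt(mu / n_rep)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se)


def test_replicate_scatter_matches_counting_statistics(broadened_response):
    """At the realistic 4.3e5 total counts, the average replicate relative
    SD over bins up to 5.7 MeV stays below 3%, and each bin's scatter is
    consistent with its Poisson expectation."""
    truth = ls.generate_true_spectrum()
    per_incident = float(broadened_response.total_efficiency @ truth.values)
    expected = ls.forward_fold(truth, broadened_response,
                               ls.DEFAULT_TOTAL_COUNTS / per_incident)
    reps = np.array([ls.sample_counts(expected, seed=s).values
                     for s in (0, 1, 2)])
    mean = reps.mean(axis=0)
    rsd = reps.std(axis=0, ddof=1) / np.where(mean > 0, mean, 1.0)
    sel = truth.grid.centers <= 5.7
    assert rsd[sel].mean() < 0.03
    poisson_floor = 1.0 / np.sqrt(np.maximum(expected.values[sel], 1.0))
    assert np.all(rsd[sel] < 6.0 * poisson_floor)
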