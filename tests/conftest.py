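"""Shared fixtures: geometry, Monte Carlo runs, and the synthetic pipeline.

The expensive Monte Carlo results are session-scoped so the efficiency
targets, monotonicity properties and end-to-end recovery tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import linacspec as ls

TABLE_HISTORIES = 500_000  # histories per efficiency validation point
RESPONSE_HISTORIES = 30_000  # histories per response-matrix column


@pytest.fixture(scope="session")
def crystal() -> ls.CrystalGeometry:
    return ls.CrystalGeometry()


@pytest.fixture(scope="session")
def broad_beam() -> ls.BeamGeometry:
    return ls.BeamGeometry(diameter=ls.BROAD_BEAM_CM)


@pytest.fixture(scope="session")
def pencil_beam() -> ls.BeamGeometry:
    return ls.BeamGeometry(diameter=ls.PENCIL_BEAM_CM)


def _run(crystal, beam, energy, seed, n=TABLE_HISTORIES):
    grid = ls.EnergyGrid(lower=0.0, width=0.2,
                         n_bins=int(np.ceil((energy + 0.4) / 0.2)))
    return ls.simulate_depositions(crystal, beam, energy, n, seed, grid=grid)


@pytest.fixture(scope="session")
def run_1mev_broad(crystal, broad_beam):
    return _run(crystal, broad_beam, 1.0, seed=101)


@pytest.fixture(scope="session")
def run_1mev_pencil(crystal, pencil_beam):
    return _run(crystal, pencil_beam, 1.0, seed=102)


@pytest.fixture(scope="session")
def run_6mev_broad(crystal, broad_beam):
    return _run(crystal, broad_beam, 6.0, seed=103)


@pytest.fixture(scope="session")
def run_20mev_broad(crystal, broad_beam):
    return _run(crystal, broad_beam, 20.0, seed=104)


@pytest.fixture(scope="session")
def pencil_response(crystal, pencil_beam) -> ls.ResponseMatrix:
    """Unbroadened 40x40 response for the collimated 0.5 cm beam."""
    return ls.build_response_matrix(
        crystal, pencil_beam, n_histories_per_column=RESPONSE_HISTORIES, seed=7)


@pytest.fixture(scope="session")
def broadened_response(pencil_response) -> ls.ResponseMatrix:
    return ls.broaden_response(pencil_response, ls.ResolutionModel())


@pytest.fixture(scope="session")
def synthetic_measurement(broadened_response):
    """Truth spectrum, expected folded counts, and one Poisson sample with
    the realistic total of 4.3e5 registered counts."""
    truth = ls.generate_true_spectrum()
    per_incident = float(broadened_response.total_efficiency @ truth.values)
    expected = ls.forward_fold(truth, broadened_response,
                               ls.DEFAULT_TOTAL_COUNTS / per_incident)
    sampled = ls.sample_counts(expected, seed=42)
    return truth, expected, sampled
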