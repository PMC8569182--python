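"""Shared fixtures: small synthetic inputs and one cached calibrated run."""

from __future__ import annotations

import numpy as np
import pytest

from neuroscales import (
    PopulationParams,
    calibrate_fic,
    generate_connectome,
    simulate_dmf,
)


@pytest.fixture(scope="session")
def params() -> PopulationParams:
    return PopulationParams()


@pytest.fixture(scope="session")
def quiet_params() -> PopulationParams:
    return PopulationParams(sigma_noise=0.0)


@pytest.fixture(scope="session")
def connectome30():
    """30-region modular connectome used by the calibration-contract checks."""
    return generate_connectome(30, 3, seed=1)


@pytest.fixture(scope="session")
def connectome20():
    return generate_connectome(20, 4, seed=3)


@pytest.fixture(scope="session")
def fic_run_g15(connectome30, params):
    """FIC-calibrated 120-s simulation at G=1.5 (shared across rate checks).

    Returns (coupling, series, per_region_mean_rates) with the first 10 s
    discarded from the rate statistics.
    """
    coupling = calibrate_fic(connectome30, params, G=1.5, seed=2)
    series = simulate_dmf(connectome30, params, coupling, duration=120.0,
                          dt=1e-4, seed=3)
    drop = int(round(10.0 / series.dt))
    rates = series.r_E[:, drop:].mean(axis=1)
    return coupling, series, rates


@pytest.fixture(scope="session")
def ground_truth_small():
    """Planted 3-network BOLD at criterion scale (snr 10, 10,000 samples)."""
    from neuroscales import generate_ground_truth_bold

    return generate_ground_truth_bold(
        n_regions=60, n_networks=3, occupancy=(0.5, 0.25, 0.25),
        dt=0.72, duration=7200.0, snr=10.0, seed=1,
    )


def greedy_match(truth: np.ndarray, estimate: np.ndarray) -> list[float]:
    """Greedy one-to-one matching of |Pearson correlation| between map sets."""
    k = truth.shape[1]
    C = np.abs(np.corrcoef(truth.T, estimate.T)[:k, k:])
    M = C.copy()
    out = []
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(M), M.shape)
        out.append(float(M[i, j]))
        M[i, :] = -1.0
        M[:, j] = -1.0
    return out
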