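import numpy as np
import pandas as pd
import pytest

from nirsel import (SimulationConfig, SpectralDataset, WavenumberGrid,
                    simulate_dataset)
from nirsel.simulate import SATURATED_REGION
from nirsel.spectra import exclude_region


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 3-sample, 5-wavenumber toy dataset."""
    grid = WavenumberGrid(np.array([9000.0, 8000.0, 7000.0, 6000.0, 5000.0]))
    absorb = np.array([[0.1, 0.2, 0.3, 0.4, 0.5],
                       [0.2, 0.3, 0.4, 0.5, 0.6],
                       [0.15, 0.25, 0.35, 0.45, 0.55]])
    meta = pd.DataFrame({"sample_id": ["A", "B", "C"],
                         "batch_id": ["B1", "B1", "B2"],
                         "time_min": [90.0, 100.0, 90.0]})
    refs = pd.DataFrame({"x1": [1.0, 2.0, 1.5], "x2": [0.5, 1.0, 0.75]})
    return SpectralDataset(absorbance=absorb, grid=grid, sample_meta=meta,
                           references=refs)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(
        seed=11, noise_sd_base=0.0, noise_sd_low_wn_region=0.0,
        scatter_slope_sd=0.0, offset_sd=0.0, tilt_sd=0.0,
        concentration_jitter_sigma=0.0, n_outliers=0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_cfg):
    return simulate_dataset(noiseless_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated campaign, saturated region excluded."""
    ds, gt = simulate_dataset(SimulationConfig(seed=5))
    return exclude_region(ds, SATURATED_REGION), gt


def planted_linear_problem(rng, n=40, p=120, informative=(10, 55, 99),
                           noise=0.0):
    """y depends linearly on a few columns of random X; others are noise."""
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[list(informative)] = [2.0, -1.5, 1.0]
    y = X @ beta + noise * rng.normal(size=n)
    return X, y
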