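"""Shared fixtures: small simulated plates reused across test modules."""

import warnings

import numpy as np
import pytest

from rhizotrack.config import PipelineConfig
from rhizotrack.simulate import SimParams, simulate_architecture, \
    rasterize_timeseries, simulate_plate
from rhizotrack.validate import benchmark_config

warnings.filterwarnings("ignore", message="stack carries no registration")


def small_params(**overrides) -> SimParams:
    """A small plate: 2 plants, 10 observations, quick to rasterize."""
    base = dict(n_plants=2, n_timesteps=10, image_shape=(420, 300),
                px_size_um=130.0, primary_rate=(0.35, 0.03),
                lateral_rate=(0.12, 0.03), lateral_density=0.12,
                crossing_bias=0.0, noise_sd=0.0, jitter=(0.0, 0.0),
                artifact_rate=0.0, seed=42)
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def clean_plate():
    """Noise-free, jitter-free, artifact-free plate with laterals."""
    return simulate_plate(small_params())


@pytest.fixture(scope="session")
def noisy_plate():
    """Same architecture as clean_plate but with sensor noise."""
    params = small_params(noise_sd=3.0)
    model = simulate_architecture(params)
    return rasterize_timeseries(model, params)


@pytest.fixture(scope="session")
def plate_config(clean_plate) -> PipelineConfig:
    return benchmark_config(clean_plate.params)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
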