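"""Shared fixtures: small, fast pipeline runs reused across test modules."""
import numpy as np
import pytest

from dmicrt.phantom import build_digital_phantom
from dmicrt.pipeline import PipelineConfig, run_reconstruct_quantify, run_simulate


SMALL_MATRIX = (12, 12, 11)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(
        scheme="bSSFP", matrix=SMALL_MATRIX, seed=0, noise_sd=0.0,
        times_min=(0.0, 70.0),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return run_simulate(small_config)


@pytest.fixture(scope="session")
def small_result(small_config, small_bundle):
    return run_reconstruct_quantify(
        small_bundle.datasets, small_bundle.phantom, small_config
    )


@pytest.fixture(scope="session")
def small_phantom():
    return build_digital_phantom(grid=SMALL_MATRIX, seed=0)


@pytest.fixture(scope="session")
def fid_config() -> PipelineConfig:
    return PipelineConfig(
        scheme="spoiledFID", matrix=SMALL_MATRIX, seed=0, noise_sd=0.0,
        times_min=(0.0, 70.0),
    )


@pytest.fixture(scope="session")
def fid_bundle(fid_config):
    return run_simulate(fid_config)


@pytest.fixture(scope="session")
def fid_result(fid_config, fid_bundle):
    return run_reconstruct_quantify(fid_bundle.datasets, fid_bundle.phantom, fid_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
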