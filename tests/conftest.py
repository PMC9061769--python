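"""Shared fixtures: synthetic configurations and cached pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from amdvir.pipeline import run_pipeline
from amdvir.synthetic import SimulationConfig, simulate_dataset, simulate_sequences


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(**overrides) -> SimulationConfig:
    """A 30-sample community, the scale used for end-to-end checks."""
    kwargs = dict(seed=11, n_sites=10, samples_per_site=3)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def tiny_config(**overrides) -> SimulationConfig:
    """A minimal community for fast structural tests."""
    kwargs = dict(
        seed=7,
        n_sites=4,
        samples_per_site=2,
        n_host_phyla=2,
        hosts_per_phylum=2,
        viruses_per_host=1,
        divergence_levels=(0.03,),
        n_background_viruses=2,
        n_background_hosts=1,
        generalist_extra_links=1,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_sequences():
    return simulate_sequences(small_config())


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline on the 30-sample noisy community."""
    out = tmp_path_factory.mktemp("pipeline_noisy")
    report = run_pipeline(out, seed=11, sim_config=small_config())
    return out, report


@pytest.fixture(scope="session")
def pipeline_run_noisefree(tmp_path_factory):
    """Full pipeline on the 30-sample community in the noise-free limit."""
    out = tmp_path_factory.mktemp("pipeline_noisefree")
    report = run_pipeline(out, seed=11, sim_config=small_config(noise_sd=0.0))
    return out, report
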