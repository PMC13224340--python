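"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ecotyper.pipeline import preprocess_chain, run_all
from ecotyper.synthio import SynthConfig, generate_cog_table, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset (200 samples, 800 ASVs)."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller dataset for cheap unit tests."""
    return generate_dataset(
        SynthConfig(seed=2, n_samples=60, n_asvs=120, depth=20_000, singleton_count=5)
    )


@pytest.fixture(scope="session")
def default_tables(default_dataset):
    """(relative, hellinger) tables from the default dataset."""
    return preprocess_chain(default_dataset)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-seed pipeline run, shared by integration tests."""
    return run_all(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
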