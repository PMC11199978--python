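"""Shared fixtures: a small synthetic multiome and deterministic RNGs."""
from __future__ import annotations

import numpy as np
import pytest

from rootlink import SimConfig, generate_multiome


@pytest.fixture()
def rng():
    return np.random.default_rng(20240311)


SMALL_CONFIG = dict(
    n_cells_per_condition=300,
    n_genes=80,
    n_peaks=200,
    n_planted_links=6,
    n_stress_only_links=4,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete paired dataset."""
    return generate_multiome(SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(**SMALL_CONFIG)
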