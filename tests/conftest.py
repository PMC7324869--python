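"""Shared fixtures: synthetic umbrella data and ideal backbone structures."""

import numpy as np
import pytest

import s100kit as sk


@pytest.fixture(scope="session")
def double_well():
    return sk.default_double_well()


@pytest.fixture(scope="session")
def umbrella_windows(double_well):
    """49 windows x 10^4 samples from the double-well fixture (seeded)."""
    return sk.sample_umbrella_windows(
        double_well, sk.SamplerParams(seed=1, n_samples=10_000))


@pytest.fixture(scope="session")
def wham_profile(umbrella_windows):
    return sk.wham(umbrella_windows)


@pytest.fixture(scope="session")
def bootstrap_profile(umbrella_windows):
    return sk.bootstrap_error(umbrella_windows, n_trials=30, seed=2)


@pytest.fixture(scope="session")
def ideal_helix():
    return sk.build_helix_coords(20)


@pytest.fixture(scope="session")
def extended_chain():
    return sk.build_helix_coords(20, 180.0, 180.0)
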