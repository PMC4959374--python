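"""Shared fixtures: small synthetic sessions and feature datasets.

The heavy end-to-end dataset (20 videos per rating through the full
pipeline) is session-scoped so the separability and chance-level checks
share one extraction run.
"""

import warnings

import numpy as np
import pytest

from adlike import generate_feature_dataset, generate_session


@pytest.fixture(scope="session")
def separable_features():
    """Full-pipeline feature matrix with disjoint class-conditional
    band-power signatures: 20 x 5 videos of 22 s -> 300 windows."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_feature_dataset(20, "separable", seed=11)


@pytest.fixture(scope="session")
def small_separable_features():
    """Cheaper separable dataset for contract and recovery tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_feature_dataset(4, "separable", seed=7)


@pytest.fixture(scope="session")
def short_session():
    """Three-video session with the default (overlapping) signature."""
    return generate_session([2, 3, 5], durations_s=[22.0, 30.0, 22.0], seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
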