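"""Shared fixtures: small synthetic sessions and toy feature sets.

Session fixtures use a reduced montage (8 channels) and reduced block
counts where the property under test does not depend on the full design
size; the acceptance suite runs the full 32-channel design.
"""

import numpy as np
import pytest

from p300balance.preprocess import FeatureDataset, session_features
from p300balance.synth import SyntheticConfig, generate_session, generate_toy_2d


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_channels=8, n_stimuli=4, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_features(small_session):
    return session_features(small_session)


@pytest.fixture(scope="session")
def overlap_toy():
    """Overlapping 2-D clusters, 40 minority / 120 majority."""
    return generate_toy_2d(40, 120, separation=1.0, seed=3)


@pytest.fixture(scope="session")
def separated_toy():
    """Widely separated 2-D clusters: no borderline structure."""
    return generate_toy_2d(30, 90, separation=50.0, seed=4)


@pytest.fixture()
def toy_features(overlap_toy) -> FeatureDataset:
    return FeatureDataset(
        X=overlap_toy.points.copy(),
        y=overlap_toy.labels.copy(),
        block_id=np.zeros(len(overlap_toy.labels), dtype=int),
        stimulus_id=np.arange(len(overlap_toy.labels)),
    )
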