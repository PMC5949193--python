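"""Shared fixtures: phantom datasets and trained models.

The heavier artifacts (the 50-image training set, the trained cascade and
AAM) are session-scoped so the full suite trains each model exactly once.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from spineseg import pipeline
from spineseg.synthetic import generate_dataset

logging.getLogger("spineseg").setLevel(logging.WARNING)

TRAIN_SEED = 11
TEST_SEED = 99


@pytest.fixture(scope="session")
def default_config():
    return pipeline.resolve_config()


@pytest.fixture(scope="session")
def train_manifest():
    """The 50-image phantom training set."""
    return generate_dataset(50, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def test_manifest():
    """A disjoint 12-image phantom test set."""
    return generate_dataset(12, seed=TEST_SEED)


@pytest.fixture(scope="session")
def small_manifest():
    """A small set for unit-level model building."""
    return generate_dataset(10, seed=21)


@pytest.fixture(scope="session")
def detector_model(train_manifest, default_config):
    """Cascade trained once on the 50-image phantom set."""
    return pipeline.train_detector(train_manifest, default_config, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def aam_model(train_manifest, default_config):
    """Patch AAM trained once on the 50-image phantom set."""
    return pipeline.train_aam(train_manifest, default_config)


@pytest.fixture(scope="session")
def small_aam(small_manifest, default_config):
    """Cheaper AAM (10 images) for unit tests that only need a valid model."""
    return pipeline.train_aam(small_manifest, default_config)


@pytest.fixture(scope="session")
def preprocessed_test_items(test_manifest, default_config):
    """Test images after the standard initial filtration."""
    out = []
    for item in test_manifest["items"]:
        pre = pipeline.preprocess_image(item["image"], default_config)
        out.append({"image": pre, "raw": item["image"], "truths": item["truths"]})
    return out


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
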