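"""Shared fixtures: small synthetic libraries and a trained model.

Everything is generated programmatically — no data files ship with the
test suite.  The expensive fixtures are session-scoped so the classifier
is trained once.
"""

from __future__ import annotations

import pytest

import ramanmp as rm


@pytest.fixture(scope="session")
def params() -> rm.PreprocessParams:
    return rm.PreprocessParams()


@pytest.fixture(scope="session")
def high_snr_library() -> rm.TrainingLibrary:
    """Clean 11-class library: separable by construction."""
    return rm.generate_training_library(n_per_class=12, snr_range=(15, 30), seed=11)


@pytest.fixture(scope="session")
def prepped_library(high_snr_library, params) -> rm.TrainingLibrary:
    return rm.preprocess_library(high_snr_library, params)


@pytest.fixture(scope="session")
def model(prepped_library) -> rm.ClassifierModel:
    """A modest forest (200 trees) trained on the clean library."""
    return rm.train(prepped_library, n_trees=200, seed=7)
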