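import warnings

import numpy as np
import pytest

from confacc import CategoryModel, CohortSpec, NeuralSpec, ObserverParams, generate_cohort


@pytest.fixture(scope="session")
def model() -> CategoryModel:
    return CategoryModel()


@pytest.fixture(scope="session")
def params() -> ObserverParams:
    return ObserverParams()


@pytest.fixture(scope="session")
def small_cohort():
    """Behaviour-only cohort: 3 subjects x 20 sequences, covert bound on."""
    spec = CohortSpec(
        n_subjects=3, n_sequences=20, include_epochs=False, covert_bound=True, seed=42
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(spec)


@pytest.fixture(scope="session")
def epoch_cohort():
    """Small cohort with neural epochs for decoding-pipeline tests."""
    spec = CohortSpec(
        n_subjects=3, n_sequences=16, include_epochs=True, covert_bound=True, seed=7,
        neural=NeuralSpec(n_channels=16, fs=64.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(spec)


@pytest.fixture(scope="session")
def triad_cohort():
    """The covert-bound study cohort used by the end-to-end qualitative checks.

    16 observers x 80 sequences with stimulus- and response-locked epochs at
    a 16-channel, 64 Hz desk-scale forward model.
    """
    spec = CohortSpec(
        n_subjects=16, n_sequences=80, include_epochs=True, covert_bound=True,
        seed=0, neural=NeuralSpec(n_channels=16, fs=64.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(spec)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
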