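import logging

import numpy as np
import pytest

from anthospec.preprocess import preprocess_pipeline
from anthospec.simulate import GeneratorParams, generate_dataset

logging.getLogger("anthospec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A 50-sample survey (2 per cell): cheap enough for most tests."""
    params = GeneratorParams(n_per_cell=2)
    spectra, table = generate_dataset(params, seed=42)
    return params, spectra, table


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    _, spectra, table = small_dataset
    return preprocess_pipeline(spectra), table


@pytest.fixture(scope="session")
def default_dataset():
    """The full default survey (300 samples), shared across heavy tests."""
    params = GeneratorParams()
    spectra, table = generate_dataset(params, seed=1)
    return params, spectra, table


@pytest.fixture(scope="session")
def default_preprocessed(default_dataset):
    _, spectra, table = default_dataset
    return preprocess_pipeline(spectra), table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
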