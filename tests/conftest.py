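"""Shared fixtures: one small synthetic cohort carried through the pipeline.

The cohort is deliberately small (70 spectra) so the whole suite stays
fast; the acceptance tests build their own full-size cohort.
"""

from __future__ import annotations

import numpy as np
import pytest

from fcdraman.peaks import PeakConfig, features_from_spectra
from fcdraman.preprocess import PreprocessConfig, run_preprocessing
from fcdraman.synthetic import (
    default_instrument,
    default_profiles,
    simulate_dataset,
)

SMALL_COUNTS = {"normal": 30, "FCD_IIa": 20, "FCD_IIb": 20}


@pytest.fixture(scope="session")
def profiles():
    return default_profiles(effect_scale=3.0)


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def small_dataset(profiles, instrument):
    return simulate_dataset(profiles, instrument, counts=SMALL_COUNTS, seed=11)


@pytest.fixture(scope="session")
def preprocessed(small_dataset):
    spectra, audit = run_preprocessing(small_dataset.spectra, small_dataset.refs,
                                       PreprocessConfig())
    return spectra, audit


@pytest.fixture(scope="session")
def small_features(preprocessed):
    spectra, _ = preprocessed
    return features_from_spectra(spectra, PeakConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
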