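"""Shared fixtures: a study-like synthetic dataset and its reference fit."""

from __future__ import annotations

import numpy as np
import pytest

from vancopk.estimation import fit_model
from vancopk.model import final_model, final_model_spec
from vancopk.synthetic import make_study_dataset

STUDY_SEED = 20210721


@pytest.fixture(scope="session")
def study_data():
    """58-subject / 176-observation cohort simulated from the final model."""
    ds, truth = make_study_dataset(seed=STUDY_SEED)
    return ds, truth


@pytest.fixture(scope="session")
def study_ds(study_data):
    return study_data[0]


@pytest.fixture(scope="session")
def final_popmodel():
    return final_model()


@pytest.fixture(scope="session")
def study_fit(study_ds):
    """FOCE-I fit of the final-model structure on the study-like cohort."""
    fit = fit_model(final_model_spec(), study_ds, estimate_rse=False)
    assert fit.converged
    return fit
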