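"""Shared fixtures: one synthetic study and a few fitted models per session."""

import warnings

import pytest
from hypothesis import settings

from reefnutr.config import SyntheticConfig
from reefnutr.data_io import apply_qc
from reefnutr.models import HabitatEffectModel, TraitNutrientModel
from reefnutr.synthetic import generate_all

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: reduced sampler settings for unit tests (documented in docs/methods.md)
FAST_MCMC = {"n_draws": 800, "warmup": 600}


@pytest.fixture(scope="session")
def base_config():
    return SyntheticConfig(seed=11, below_loq_fraction=0.0,
                           outlier_fraction=0.0)


@pytest.fixture(scope="session")
def study(base_config):
    """One full synthetic dataset with ground truth."""
    return generate_all(base_config)


@pytest.fixture(scope="session")
def qc_samples(study):
    filtered, _ = apply_qc(study["samples"])
    return filtered


@pytest.fixture(scope="session")
def iron_fit(qc_samples, study):
    """Family-intercept trait model fitted to synthetic iron samples."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TraitNutrientModel(nutrient="iron", seed=21,
                                  **FAST_MCMC).fit(qc_samples,
                                                   study["traits"])


@pytest.fixture(scope="session")
def calcium_fit(qc_samples, study):
    """Log-normal calcium model (log-transformed response)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TraitNutrientModel(nutrient="calcium", seed=23,
                                  **FAST_MCMC).fit(qc_samples,
                                                   study["traits"])


@pytest.fixture(scope="session")
def habitat_fits(qc_samples, study):
    """Varying-slopes habitat models for iron (effect ln 1.5) and selenium
    (no effect)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, nutrient in enumerate(("iron", "selenium")):
            out[nutrient] = HabitatEffectModel(
                nutrient=nutrient, seed=31 + i, **FAST_MCMC
            ).fit(qc_samples, study["traits"])
    return out
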