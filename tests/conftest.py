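import numpy as np
import pytest

from mammotex import pipeline, preprocess
from mammotex.phantom import PhantomParams, generate_cohort, generate_phantom

# study conditions of the synthetic benchmark: image side, ROI patch side
SIZE = 256
PATCH = 64


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free lesion-free phantom with truth masks."""
    return generate_phantom(PhantomParams(seed=42, size=SIZE, noise_gaussian_sd=0.0))


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom(
        PhantomParams(seed=43, size=SIZE, lesion="benign", noise_gaussian_sd=0.0)
    )


@pytest.fixture(scope="session")
def malign_phantom():
    return generate_phantom(
        PhantomParams(seed=44, size=SIZE, lesion="malign", noise_gaussian_sd=0.0)
    )


@pytest.fixture(scope="session")
def easy_cohort():
    """High-lesion-contrast benchmark cohort: 60 normal / 30 benign / 30 malign."""
    return generate_cohort(60, 30, 30, seed=2024, size=SIZE, contrast_range=(90, 120))


@pytest.fixture(scope="session")
def easy_features_clahe_usm(easy_cohort):
    """Feature table for the benchmark cohort under CLAHE&USM."""
    return pipeline.extract_feature_table(
        easy_cohort, "CLAHE_USM", preprocess.FilterParams(),
        patch_size=PATCH, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast mixed cohort for wiring-level tests."""
    return generate_cohort(8, 4, 4, seed=5, size=SIZE)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
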