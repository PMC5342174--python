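import numpy as np
import pandas as pd
import pytest

from acspredict import synth


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: quick to generate, rich enough for every stage."""
    return synth.SimConfig(
        n_cases=30, n_controls=30, n_peptides=120, n_true_biomarkers=10,
        n_housekeeping=8, log2_effect_mean=2.0, log2_effect_sd=0.0,
        biomarker_freq=1.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return synth.generate_catalog(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_catalog):
    cohort, truth = synth.generate_cohort(small_config, small_catalog)
    return cohort


@pytest.fixture(scope="session")
def small_matrix(small_config, small_catalog, small_cohort):
    return synth.generate_amplitude_matrix(small_config, small_catalog,
                                           small_cohort)


@pytest.fixture(scope="session")
def small_profiles(small_config, small_catalog, small_cohort):
    profiles, planted, dilution = synth.generate_profiles(
        small_config, small_catalog, small_cohort)
    return profiles, planted, dilution


@pytest.fixture()
def rng():
    return np.random.default_rng(20231108)


@pytest.fixture(scope="session")
def toy_blobs():
    """Two well-separated Gaussian blobs: linearly separable by margin."""
    r = np.random.default_rng(5)
    a = r.normal(loc=-4.0, scale=0.5, size=(25, 3))
    b = r.normal(loc=+4.0, scale=0.5, size=(25, 3))
    X = pd.DataFrame(np.vstack([a, b]),
                     index=[f"T{i:03d}" for i in range(50)],
                     columns=["f1", "f2", "f3"])
    y = pd.Series([0] * 25 + [1] * 25, index=X.index)
    return X, y
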