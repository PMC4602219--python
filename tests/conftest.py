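import numpy as np
import pytest
from dataclasses import replace

from mouseerp.pipeline import RunConfig, cohort_epochs
from mouseerp.preprocess import extract_epochs, reject_artifacts
from mouseerp.synth import default_config, null_config, simulate_animal


@pytest.fixture(scope="session")
def noise_free_config():
    """Reference templates with noise, jitter and artifacts switched off."""
    return replace(default_config(), noise_sd_uV=0.0, animal_jitter_frac=0.0,
                   artifact_prob=0.0, n_trials=8)


@pytest.fixture(scope="session")
def wt_epochs_clean(noise_free_config):
    rec = simulate_animal(noise_free_config, "WT", "WT01", seed=1)
    return extract_epochs(rec)


@pytest.fixture(scope="session")
def hypo_epochs_clean(noise_free_config):
    rec = simulate_animal(noise_free_config, "HYPO", "HY01", seed=2)
    return extract_epochs(rec)


@pytest.fixture(scope="session")
def small_cohort_epochs():
    """A small noisy cohort (6 animals × 64 trials) with the planted effect,
    artifact-rejected — shared across classifier tests."""
    cfg = RunConfig(synth=replace(default_config(), n_per_genotype=3, n_trials=64), seed=7)
    return cohort_epochs(cfg)


@pytest.fixture(scope="session")
def small_null_epochs():
    """Same size cohort with the genotype effect removed."""
    cfg = RunConfig(synth=replace(null_config(), n_per_genotype=3, n_trials=64), seed=7)
    return cohort_epochs(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
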