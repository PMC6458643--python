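import numpy as np
import pytest

from aortakit import synthetic as syn
from aortakit.core import Centreline


@pytest.fixture(scope="session")
def base_shape() -> Centreline:
    return syn.base_centreline()


@pytest.fixture(scope="session")
def clean_population():
    """60 shapes from 3 curvature + 3 radius modes, low noise, with truth."""
    cfg = syn.default_population_config(n_subjects=60, seed=11)
    cfg.noise_sd = 0.05
    shapes, truth = syn.generate_centerline_population(cfg)
    return cfg, shapes, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Full 20-subject cohort (shapes + waveforms + covariates)."""
    cfg = syn.default_cohort_config(n_subjects=20, seed=5)
    records, truth = syn.generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
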