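import numpy as np
import pytest

from proteoconcord.concordance import score_cohort
from proteoconcord.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Calibrated mid-size cohort shared across modules (seeded)."""
    cfg = SimConfig(n_genes=600, n_tumors=24, n_normals=16, seed=42)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    _, cohort, _ = small_cohort
    return score_cohort(cohort)


@pytest.fixture(scope="session")
def big_cohort():
    """2000-gene cohort for calibration-precision invariants."""
    cfg = SimConfig(n_genes=2000, n_tumors=25, n_normals=15, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
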