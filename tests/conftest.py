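import numpy as np
import pytest

import ecocost as ec
from ecocost.inference import McmcConfig


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort with known ground truth (both tasks)."""
    cfg = ec.CohortConfig(n_subjects=12, seed=42)
    trials, truth = ec.simulate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def small_effort_fit(small_cohort):
    """A converged reduced-size fit of the generating model (effort task)."""
    _, trials, _ = small_cohort
    eff = trials[trials["task"] == "effort"]
    return ec.fit_model(
        eff,
        "parabolic-2k2b",
        config=McmcConfig(chains=4, iterations=2000, warmup=1000, seed=7),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
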