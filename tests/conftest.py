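import numpy as np
import pytest

from rseeg.io import BAND_BY_NAME
from rseeg.pipeline import collect_cohort, simulated_cohort
from rseeg.synthetic import SimConfig

DELTA = BAND_BY_NAME["delta"]
THETA = BAND_BY_NAME["theta"]


@pytest.fixture(scope="session")
def effect_cohort():
    """One default-condition cohort (18+18, 300 s) with the standard effects:
    delta/theta power enhancement on middle/posterior channels and attenuated
    fronto-temporo-parietal coupling in patients."""
    cfg = SimConfig(seed=202)
    return collect_cohort(simulated_cohort(cfg), [DELTA, THETA])


@pytest.fixture(scope="session")
def reduced_effect_cohort():
    """A smaller effect cohort (10+10, 60 s) for permutation-style checks."""
    cfg = SimConfig(seed=303, n_per_group=10, duration_s=60.0)
    return collect_cohort(simulated_cohort(cfg), [DELTA, THETA])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
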