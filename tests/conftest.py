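import io

import numpy as np
import pytest

from gfrconcord import SimulationParams, simulate_cohort
from gfrconcord.synthetic import cohort_to_csv


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 300-row synthetic cohort table (default parameters)."""
    return simulate_cohort(SimulationParams(n=300, seed=11))


@pytest.fixture(scope="session")
def small_cohort_csv(small_cohort):
    return io.StringIO(cohort_to_csv(small_cohort))


def random_pairs(rng, n):
    """Random positive (egfr, mgfr) pairs for invariant checks."""
    mgfr = rng.uniform(5.0, 150.0, n)
    egfr = mgfr * np.exp(rng.normal(0.0, 0.25, n))
    return egfr, mgfr
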