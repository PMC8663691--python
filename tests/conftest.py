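import numpy as np
import pytest

from swayval import CohortConfig, generate_cohort
from swayval.sway_metrics import metrics_table


@pytest.fixture(scope="session")
def default_manifest():
    """One in-memory default cohort (20 subjects x 2 x 2 x 3 x 2 devices)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_metrics(default_manifest):
    return metrics_table(default_manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
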