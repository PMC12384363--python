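import numpy as np
import pytest

from histoprior import EventCount, McmcSettings, aggregate_groups
from histoprior.datasets import load_bap1_cohorts, load_historical_controls


@pytest.fixture(scope="session")
def cohort_table():
    return load_bap1_cohorts()


@pytest.fixture(scope="session")
def historical():
    return load_historical_controls()


@pytest.fixture(scope="session")
def totals(cohort_table):
    """Aggregated (mutant, wildtype) event counts: 2/329 and 0/227."""
    return aggregate_groups(cohort_table)


@pytest.fixture(scope="session")
def default_settings():
    return McmcSettings()


def mc_se_mean(draws: np.ndarray) -> float:
    return float(draws.std(ddof=1) / np.sqrt(len(draws)))
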