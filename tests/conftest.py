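import warnings

import pytest

from oncosubtype.simulate import default_config, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def cohort():
    """Default planted cohort, seed 1 (shared across tests; treat as read-only)."""
    return simulate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def cohort_factory():
    def make(seed, **overrides):
        return simulate_cohort(default_config(seed=seed, **overrides))

    return make
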