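import numpy as np
import pytest

from pathsurv import pathway_activity, synthetic_data


@pytest.fixture(scope="session")
def planted_cohort():
    """One simulated cohort with a single prognostic pathway among nulls."""
    config = synthetic_data.preset_scenarios(m_samples=300, seed=42)["planted"]
    x, sets, surv, truth = synthetic_data.generate(config)
    return x, sets, surv, truth


@pytest.fixture(scope="session")
def planted_standardized(planted_cohort):
    x, sets, surv, truth = planted_cohort
    return pathway_activity.preprocess(x), sets, surv, truth


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort where survival is independent of all expression."""
    config = synthetic_data.preset_scenarios(m_samples=300, seed=7)["null"]
    x, sets, surv, truth = synthetic_data.generate(config)
    return x, sets, surv, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
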