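import numpy as np
import pytest

import metanet as mn


@pytest.fixture(scope="session")
def small_config() -> mn.SimulationConfig:
    """Desk-scale cohort: 3 subjects, rest + 2 tasks, 200 frames."""
    coupling = mn.default_coupling()
    keep = {c: coupling[c] for c in ("rest", "relational", "motor")}
    return mn.SimulationConfig(
        n_subjects=3, n_frames=200, coupling=keep, seed=42
    )


@pytest.fixture(scope="session")
def cohort(small_config) -> mn.SyntheticCohort:
    return mn.simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
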