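import numpy as np
import pytest

import coinlab as cl


@pytest.fixture(scope="session")
def design() -> cl.TaskDesign:
    return cl.make_design()


def zero_noise_spec(**overrides) -> cl.CohortSpec:
    """Observers that respond with their exact posterior mean (no noise)."""
    base = dict(perceptual_noise_sd=0.0, motor_noise_sd=0.0, lapse_rate=0.0)
    base.update(overrides)
    return cl.CohortSpec(**base)


@pytest.fixture(scope="session")
def default_cohort(design) -> cl.SimulatedCohort:
    """A 200-participant cohort under the default generative conditions."""
    return cl.simulate_cohort(cl.CohortSpec(n_participants=200, seed=11), design)


@pytest.fixture(scope="session")
def default_metrics(default_cohort, design):
    return cl.compute_all_metrics(
        default_cohort.trials_main, default_cohort.trials_likonly, design
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
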