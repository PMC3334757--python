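import numpy as np
import pytest

from acetapop import (
    DoseEvent,
    PopulationParameters,
    StudyDesign,
    generate_study,
)


@pytest.fixture(scope="session")
def theta():
    """Published final-model estimates, used as simulation truth."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def small_dataset(theta):
    """A 25-subject synthetic study, shared across read-only tests."""
    return generate_study(StudyDesign(n_subjects=25), theta,
                          np.random.default_rng(314))


def random_iv_regimen(rng, max_doses=6, t_max=3.0, amt_range=(50.0, 1000.0)):
    """A random multiple-bolus regimen for property tests."""
    n = int(rng.integers(1, max_doses + 1))
    times = np.sort(rng.uniform(0.0, t_max, size=n))
    times[0] = 0.0
    amounts = rng.uniform(*amt_range, size=n)
    return [DoseEvent(float(t), float(a)) for t, a in zip(times, amounts)]
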