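import numpy as np
import pytest

from seamsel import Design, base_draws, realize


@pytest.fixture(scope="session")
def design5():
    """The worked-example design: five arms, unequal stage sizes."""
    return Design(n_arms=5, m1=28.0, m2=140.0, futility_threshold=0.0,
                  sigma=5.0, alpha=0.025)


@pytest.fixture(scope="session")
def null_draws5():
    """Shared standard-normal reservoir for five-arm null ensembles."""
    return base_draws(5, 100_000, seed=2024)


@pytest.fixture(scope="session")
def null_batch5(design5, null_draws5):
    return realize(design5, null_draws5, np.zeros(5))
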