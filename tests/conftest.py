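import numpy as np
import pytest

from banditfit.task import Session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_session(rng, subject_id="s0", n_blocks=3, trials_per_block=20,
                   group="toy") -> Session:
    n = n_blocks * trials_per_block
    return Session(
        subject_id=subject_id,
        group=group,
        blocks=np.repeat(np.arange(n_blocks), trials_per_block),
        actions=rng.integers(0, 2, n),
        rewards=rng.integers(0, 2, n),
    )


@pytest.fixture
def toy_cohort(rng):
    """Three random 60-trial subjects (3 blocks x 20 trials)."""
    return [random_session(rng, f"s{i}") for i in range(3)]
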