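import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pubsim import Journal

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def make_journal(t_min=0.5, t_max=0.7, reputation=0.8, rank=0.0, jid=0, ar=None,
                 group=None) -> Journal:
    return Journal(id=jid, reputation=reputation, t_min=t_min, t_max=t_max,
                   group_id=group, ar=ar, reputation_rank_fraction=rank)


@pytest.fixture
def journal():
    return make_journal()
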