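import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sym_pair_run():
    """One completed symmetric-pair run, shared by sampler/diagnostics tests."""
    import ladybugs as lb

    cfg = lb.make_symmetric_pair_config(7, total_gibbs_steps=2000)
    cfg.schedule.replicates = 2
    cfg.schedule.snapshot_every = 500
    return cfg, lb.run_ladybugs(cfg)
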