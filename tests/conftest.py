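import numpy as np
import pytest

from painlearn.models import ModelSpec, SubjectParams
from painlearn.synth import WalkConfig, generate_schedule, simulate_agent


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(WalkConfig(seed=11))


@pytest.fixture(scope="session")
def short_schedule():
    return generate_schedule(WalkConfig(n_trials=80, n_runs=2, seed=7))


@pytest.fixture(scope="session")
def agent_dataset(schedule):
    spec = ModelSpec.from_id(1)
    params = SubjectParams.from_rates(spec, R=5.0, P=4.0, lr_r=0.5, lr_p=0.4,
                                      d=0.2, xi=0.1)
    return simulate_agent(spec, params, schedule, seed=3)


def random_params(spec, rng, stable=False):
    """Admissible random parameters; ``stable`` keeps LR*sensitivity <= ~1."""
    hi = 6.0 if stable else 30.0
    lr_hi = 0.3 if stable else 1.0
    return SubjectParams.from_rates(
        spec,
        R=rng.uniform(0, hi), P=rng.uniform(0, hi),
        lr_r=rng.uniform(0, lr_hi), lr_p=rng.uniform(0, lr_hi),
        d=rng.uniform(0, 1) if spec.has_decay else 0.0,
        xi=rng.uniform(0, 1) if spec.has_lapse else 0.0,
    )
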