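import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bntopo import BNPModel, TopologySpace, UnknownEntrySet, encode_observations, mask_missing, simulate


def random_model(d: int, p: float, rng: np.random.Generator) -> BNPModel:
    return BNPModel(
        C=rng.integers(-1, 2, size=(d, d)),
        b=rng.choice([-0.5, 0.5], size=d),
        p=p,
    )


@pytest.fixture(scope="session")
def toy3_space():
    """d=4 network with 3 unknown entries (27 candidates)."""
    rng = np.random.default_rng(42)
    base = random_model(4, 0.1, rng)
    unknowns = UnknownEntrySet(((1, 2), (2, 3), (3, 1)))
    return TopologySpace(base, unknowns)


@pytest.fixture(scope="session")
def cell_cycle():
    from bntopo.networks import cell_cycle_model, cell_cycle_space

    space, truth = cell_cycle_space(0.1)
    return cell_cycle_model(0.1), space, truth


def make_masked_data(model, T, fraction, seed):
    sim_rng, mask_rng = np.random.default_rng(seed).spawn(2)
    traj = mask_missing(simulate(model, T, seed=sim_rng), fraction, seed=mask_rng)
    return traj, encode_observations(traj)
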