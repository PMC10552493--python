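import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bound_pair_system():
    """Two particles bound by the 12-6-4 well (minimum near r = 2)."""
    from ionfes.potentials import ToySystem, lj_124_from_well, pair_key

    table = {pair_key("ion", "ligand_oxygen"): lj_124_from_well(2.0, 4.0)}
    return ToySystem(
        positions=np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
        roles=["ion", "ligand_oxygen"],
        charges=np.array([4.0, -0.5]),
        masses=np.ones(2),
        pair_table=table,
    )


@pytest.fixture
def chelator_system():
    from ionfes.synthetic import build_toy_chelator

    system, cv_lig, cv_sol = build_toy_chelator(n_groups=3, seed=7, n_solvent=6)
    return system, cv_lig, cv_sol
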