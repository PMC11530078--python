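import numpy as np
import pytest

from dyadgames import scenario_staghunt, scenario_viapoint
from dyadgames.game_core import PlayerGameSpec, StrategyBlocks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def staghunt_game():
    return scenario_staghunt.build(scenario_staghunt.StagHuntConfig())


@pytest.fixture(scope="session")
def viapoint_basis():
    return scenario_viapoint.build_basis()


@pytest.fixture(scope="session")
def viapoint_game(viapoint_basis):
    return scenario_viapoint.assemble_game(scenario_viapoint.ViaPointConfig(),
                                           viapoint_basis)


def random_spec(rng, n_own=2, n_other=2, n_strategies=2):
    """Random positive-definite quadratic game spec for one player."""
    blocks = {}
    for k in range(n_strategies):
        B = rng.normal(size=(n_own, n_own))
        Q_own = B @ B.T + n_own * np.eye(n_own)
        C = rng.normal(size=(n_other, n_other))
        blocks[f"s{k}"] = StrategyBlocks(
            Q_own=Q_own,
            Q_cross=rng.normal(size=(n_own, n_other)),
            Q_other=C @ C.T,
            r_own=rng.normal(size=n_own),
            r_other=rng.normal(size=n_other),
            z=float(rng.normal()))
    return PlayerGameSpec(n_own, n_other, blocks)
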