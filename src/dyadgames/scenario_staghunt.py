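"""Spatial Stag Hunt as a one-dimensional two-strategy quadratic game.

Two players each move a cursor along a line toward either a rabbit position
``u_R`` (safe, partner-independent payoff) or a stag position ``u_S``
(better payoff, but only if both players go there).  The discrete strategy
``s`` is 1 for the rabbit branch and 0 for the stag branch, and the cost
blocks per strategy are

    Q_own   = s w + 2 (1-s) w
    Q_cross = -(1-s) w
    Q_other = (1-s) w
    r_own   = -s w u_R - (1-s) w u_S
    r_other = 0
    z       = s (w u_R^2 / 2 + z_R) + (1-s) (w u_S^2 / 2 + z_S)

The curvature weight ``w`` and offsets ``z_R``, ``z_S`` are calibrated so the
game reproduces a prescribed cost matrix at the four corner configurations:
z_R is the rabbit cost (partner-independent), z_S the mutual-stag cost, and
w = 2 (J(S,R) - z_S) / |u_R - u_S|^2 makes a lone stag hunter's cost equal
J(S,R).

An alternative stag branch, w(|u_i - u_S|^2 + |u_-i - u_S|^2)/2, penalizing
each player's distance to the stag rather than the inter-player distance, is
available via ``literal_cost=True``; the two forms agree on all four matrix
corners and differ only off them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game_core import JointGame, PlayerGameSpec, StrategyBlocks
from .partner_model import PlayerParams

__all__ = ["RABBIT", "STAG", "StagHuntConfig", "calibrate", "build",
           "DEFAULT_COST_MATRIX", "baseline_params"]

RABBIT = "rabbit"   # s = 1
STAG = "stag"       # s = 0

# corner costs (J(R,R), J(R,S), J(S,R), J(S,S)): the rabbit is safe at 5,
# a lone stag hunter pays 10, mutual stag pays 1
DEFAULT_COST_MATRIX = {"RR": 5.0, "RS": 5.0, "SR": 10.0, "SS": 1.0}


def calibrate(cost_matrix: dict, u_R: float, u_S: float) -> tuple[float, float, float]:
    """Calibrate (w, z_R, z_S) from the corner cost matrix and target spacing.

    The rabbit corners pin z_R directly, the mutual-stag corner pins z_S, and
    the lone-stag corner fixes the curvature w.
    """
    if u_R == u_S:
        raise ValueError("rabbit and stag positions must differ")
    z_R = float(cost_matrix["RR"])
    if "RS" in cost_matrix and not np.isclose(cost_matrix["RS"], z_R):
        raise ValueError("rabbit cost must be partner-independent "
                         "(J(R,R) must equal J(R,S))")
    z_S = float(cost_matrix["SS"])
    w = 2.0 * (float(cost_matrix["SR"]) - z_S) / (u_R - u_S) ** 2
    return w, z_R, z_S


@dataclass
class StagHuntConfig:
    """Geometry, cost matrix and baseline player parameters of the scenario.

    Default positions are symmetric about the origin with |u_R - u_S| = 2,
    the spacing under which the default cost matrix calibrates to w = 9/2.
    The symmetric placement makes the default prior mean mu = 0 a neutral
    midpoint belief rather than a belief pinned on either target.
    """

    u_R: float = -1.0
    u_S: float = 1.0
    cost_matrix: dict = field(default_factory=lambda: dict(DEFAULT_COST_MATRIX))
    literal_cost: bool = False

    def __post_init__(self):
        if self.u_R == self.u_S:
            raise ValueError("rabbit and stag positions must differ")
        cm = self.cost_matrix
        if not (cm["SR"] > cm["RR"] > cm["SS"]):
            raise ValueError("cost matrix lacks stag-hunt structure: "
                             "need J(S,R) > J(R,.) > J(S,S)")

    def calibrated(self) -> tuple[float, float, float]:
        return calibrate(self.cost_matrix, self.u_R, self.u_S)


def _player_spec(w: float, z_R: float, z_S: float, u_R: float, u_S: float,
                 literal: bool) -> PlayerGameSpec:
    # rabbit branch (s=1): partner-independent quadratic well at u_R
    rabbit = StrategyBlocks(
        Q_own=[[w]], Q_cross=[[0.0]], Q_other=[[0.0]],
        r_own=[-w * u_R], r_other=[0.0], z=0.5 * w * u_R**2 + z_R)
    if literal:
        # stag branch: wells at u_S for both players
        stag = StrategyBlocks(
            Q_own=[[w]], Q_cross=[[0.0]], Q_other=[[w]],
            r_own=[-w * u_S], r_other=[-w * u_S],
            z=w * u_S**2 + z_S)
    else:
        # stag branch: own well at u_S plus inter-player coupling
        stag = StrategyBlocks(
            Q_own=[[2.0 * w]], Q_cross=[[-w]], Q_other=[[w]],
            r_own=[-w * u_S], r_other=[0.0],
            z=0.5 * w * u_S**2 + z_S)
    return PlayerGameSpec(1, 1, {RABBIT: rabbit, STAG: stag})


def build(config: StagHuntConfig) -> JointGame:
    """Build the calibrated two-player game (identical specs per player)."""
    w, z_R, z_S = config.calibrated()
    spec = _player_spec(w, z_R, z_S, config.u_R, config.u_S,
                        config.literal_cost)
    return JointGame(spec, spec)


def baseline_params(sigma_y: float = 0.1, sigma_x: float = 0.1) -> PlayerParams:
    """Baseline simulation parameters of the scenario.

    mu = 0, P0 = 1e-6 (near-deterministic midpoint prior), A = 0.99,
    lambda1 = 0.1, a = 0.999; sensory and internal noise levels are the
    sweep factors (0.1 = low, 10 = high).
    """
    return PlayerParams(sigma_y=sigma_y, mu=0.0, p0=1e-6, retention=0.99,
                        sigma_x=sigma_x, lambda1=0.1, decay=0.999)
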