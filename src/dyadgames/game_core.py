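"""Quadratic games with discrete strategy choice.

A two-player quadratic game assigns each player ``i`` a cost that is quadratic
in both players' continuous actions.  With a discrete decision variable
``s`` (the strategy) selecting among ``M`` cost branches, player ``i``'s cost is

    J_i(u_i, u_-i, s) = 1/2 u_i' Q_own(s) u_i + u_i' Q_cross(s) u_-i
                        + 1/2 u_-i' Q_other(s) u_-i
                        + r_own(s)' u_i + r_other(s)' u_-i + z(s)

When every own-curvature block ``Q_own(s)`` is symmetric positive definite the
game restricted to a joint strategy pair has a unique Nash equilibrium with a
closed form, and the expected cost under a Gaussian belief about the partner's
action is again an explicit quadratic in the own action.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np

__all__ = [
    "PlayerGameSpec",
    "JointGame",
    "ExpectedCostDecomposition",
    "deterministic_cost",
    "nash_equilibrium",
    "expected_cost",
    "pure_strategy_equilibria",
]

_COND_LIMIT = 1e12


def _as_matrix(a, rows: int, cols: int, name: str) -> np.ndarray:
    m = np.atleast_2d(np.asarray(a, dtype=float))
    if m.shape != (rows, cols):
        raise ValueError(f"{name} must have shape {(rows, cols)}, got {m.shape}")
    return m


def _as_vector(a, n: int, name: str) -> np.ndarray:
    v = np.asarray(a, dtype=float).reshape(-1)
    if v.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got {v.shape}")
    return v


@dataclass(frozen=True)
class StrategyBlocks:
    """Cost blocks of one strategy branch of a player's quadratic cost."""

    Q_own: np.ndarray
    Q_cross: np.ndarray
    Q_other: np.ndarray
    r_own: np.ndarray
    r_other: np.ndarray
    z: float = 0.0


class PlayerGameSpec:
    """One player's quadratic cost, one set of blocks per strategy.

    Parameters
    ----------
    n_own, n_other : int
        Dimensions of the player's own and the partner's action vectors.
    blocks : mapping from strategy label to StrategyBlocks (or dict of arrays)
        The quadratic cost blocks per strategy.  ``Q_own`` must be symmetric
        positive definite (and well conditioned) for every strategy; the
        Gaussian form of the expected cost and of the stochastic action
        distribution is only valid in that case, so competitive (indefinite)
        games are rejected outright.
    """

    def __init__(self, n_own: int, n_other: int,
                 blocks: Mapping[Hashable, StrategyBlocks | Mapping]):
        if n_own < 1 or n_other < 1:
            raise ValueError("action dimensions must be >= 1")
        if len(blocks) < 1:
            raise ValueError("at least one strategy is required")
        self.n_own = int(n_own)
        self.n_other = int(n_other)
        self.strategies: tuple[Hashable, ...] = tuple(blocks.keys())
        self._blocks: dict[Hashable, StrategyBlocks] = {}
        for s, b in blocks.items():
            if isinstance(b, Mapping):
                b = StrategyBlocks(**b)
            Q_own = _as_matrix(b.Q_own, n_own, n_own, f"Q_own[{s}]")
            Q_cross = _as_matrix(b.Q_cross, n_own, n_other, f"Q_cross[{s}]")
            Q_other = _as_matrix(b.Q_other, n_other, n_other, f"Q_other[{s}]")
            r_own = _as_vector(b.r_own, n_own, f"r_own[{s}]")
            r_other = _as_vector(b.r_other, n_other, f"r_other[{s}]")
            if not np.allclose(Q_own, Q_own.T, atol=1e-10):
                raise ValueError(f"Q_own[{s}] must be symmetric")
            if not np.allclose(Q_other, Q_other.T, atol=1e-10):
                raise ValueError(f"Q_other[{s}] must be symmetric")
            w = np.linalg.eigvalsh(0.5 * (Q_own + Q_own.T))
            if w[0] <= 0.0:
                raise ValueError(
                    f"Q_own[{s}] is not positive definite (min eigenvalue "
                    f"{w[0]:.3g}); indefinite/competitive cost branches are "
                    "unsupported")
            if w[-1] / w[0] > _COND_LIMIT:
                raise ValueError(
                    f"Q_own[{s}] is near-singular (condition number "
                    f"{w[-1] / w[0]:.3g} > {_COND_LIMIT:.0e})")
            self._blocks[s] = StrategyBlocks(
                Q_own=0.5 * (Q_own + Q_own.T), Q_cross=Q_cross,
                Q_other=0.5 * (Q_other + Q_other.T),
                r_own=r_own, r_other=r_other, z=float(b.z))

    def blocks(self, s: Hashable) -> StrategyBlocks:
        try:
            return self._blocks[s]
        except KeyError:
            raise KeyError(f"unknown strategy label {s!r}; "
                           f"known: {list(self.strategies)}") from None

    @property
    def n_strategies(self) -> int:
        return len(self.strategies)

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_own": self.n_own,
            "n_other": self.n_other,
            "strategies": {
                str(s): {
                    "Q_own": b.Q_own.tolist(),
                    "Q_cross": b.Q_cross.tolist(),
                    "Q_other": b.Q_other.tolist(),
                    "r_own": b.r_own.tolist(),
                    "r_other": b.r_other.tolist(),
                    "z": b.z,
                } for s, b in self._blocks.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlayerGameSpec":
        blocks = {s: StrategyBlocks(
            Q_own=np.asarray(bb["Q_own"], dtype=float),
            Q_cross=np.asarray(bb["Q_cross"], dtype=float),
            Q_other=np.asarray(bb["Q_other"], dtype=float),
            r_own=np.asarray(bb["r_own"], dtype=float),
            r_other=np.asarray(bb["r_other"], dtype=float),
            z=float(bb["z"])) for s, bb in d["strategies"].items()}
        return cls(int(d["n_own"]), int(d["n_other"]), blocks)


@dataclass(frozen=True)
class ExpectedCostDecomposition:
    """Expected cost under a Gaussian partner belief, completed-square form.

    E{J(u, u_-i, s)} over u_-i ~ N(x, P) equals
    ``1/2 (u - u_star)' Q_own (u - u_star) + q``; ``q`` carries the belief
    uncertainty through the ``1/2 trace(Q_other P)`` term.
    """

    u_star: np.ndarray
    q: float
    Q_own: np.ndarray

    def value(self, u) -> float:
        d = np.asarray(u, dtype=float).reshape(-1) - self.u_star
        return float(0.5 * d @ self.Q_own @ d + self.q)


def deterministic_cost(spec: PlayerGameSpec, u_own, u_other, s) -> float:
    """Evaluate the quadratic cost at realized actions under strategy ``s``."""
    b = spec.blocks(s)
    u1 = _as_vector(u_own, spec.n_own, "u_own")
    u2 = _as_vector(u_other, spec.n_other, "u_other")
    return float(0.5 * u1 @ b.Q_own @ u1 + u1 @ b.Q_cross @ u2
                 + 0.5 * u2 @ b.Q_other @ u2
                 + b.r_own @ u1 + b.r_other @ u2 + b.z)


def expected_cost(spec: PlayerGameSpec, x, P, s) -> ExpectedCostDecomposition:
    """Expected cost over the partner belief ``u_-i ~ N(x, P)``.

    Uses the Gaussian quadratic-expectation identity
    ``E[u'Qu] = x'Qx + trace(QP)``.  Returns the conditional optimum
    ``u_star = -Q_own^{-1}(Q_cross x + r_own)`` and the residual ``q`` such
    that the decomposition reproduces the full expectation.
    """
    b = spec.blocks(s)
    x = _as_vector(x, spec.n_other, "x")
    P = _as_matrix(P, spec.n_other, spec.n_other, "P")
    if not np.allclose(P, P.T, atol=1e-9):
        raise ValueError("P must be symmetric")
    if np.linalg.eigvalsh(0.5 * (P + P.T))[0] < -1e-9:
        raise ValueError("P must be positive semidefinite")
    rhs = b.Q_cross @ x + b.r_own
    u_star = -np.linalg.solve(b.Q_own, rhs)
    # q = E{J}(u_star): the value of the expectation at its minimizer.
    q = (0.5 * x @ b.Q_other @ x + 0.5 * np.trace(b.Q_other @ P)
         + b.r_other @ x + b.z - 0.5 * u_star @ b.Q_own @ u_star)
    return ExpectedCostDecomposition(u_star=u_star, q=float(q), Q_own=b.Q_own)


class JointGame:
    """Both players' specs with the stacked first-order-condition system.

    For a joint strategy pair the stacked system is

        R = [[Q_own^1,   Q_cross^1],
             [Q_cross^2, Q_own^2  ]],     r = [r_own^1, r_own^2]

    (each player's row is the gradient of their own cost in their own action)
    and the unique Nash equilibrium is ``u* = -R^{-1} r``.
    """

    def __init__(self, spec1: PlayerGameSpec, spec2: PlayerGameSpec):
        if spec1.n_other != spec2.n_own or spec2.n_other != spec1.n_own:
            raise ValueError("player specs have inconsistent action dimensions")
        self.spec1 = spec1
        self.spec2 = spec2

    @property
    def specs(self) -> tuple[PlayerGameSpec, PlayerGameSpec]:
        return (self.spec1, self.spec2)

    def joint_strategies(self) -> list[tuple[Hashable, Hashable]]:
        return [(s1, s2) for s1 in self.spec1.strategies
                for s2 in self.spec2.strategies]

    def stacked_system(self, joint_strategy) -> tuple[np.ndarray, np.ndarray]:
        s1, s2 = joint_strategy
        b1 = self.spec1.blocks(s1)
        b2 = self.spec2.blocks(s2)
        R = np.block([[b1.Q_own, b1.Q_cross], [b2.Q_cross, b2.Q_own]])
        r = np.concatenate([b1.r_own, b2.r_own])
        return R, r


def nash_equilibrium(game: JointGame, joint_strategy) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Nash equilibrium of the game at a fixed joint strategy.

    Returns (u1*, u2*).  Raises ``numpy.linalg.LinAlgError`` when the stacked
    system is singular (no unique equilibrium).
    """
    R, r = game.stacked_system(joint_strategy)
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"stacked game matrix is singular or near-singular (cond={cond:.3g})")
    u = -np.linalg.solve(R, r)
    n1 = game.spec1.n_own
    return u[:n1], u[n1:]


def pure_strategy_equilibria(game: JointGame, tol: float = 1e-9,
                             deviation: str = "equilibrium") -> list[tuple]:
    """Joint strategy pairs that are pure Nash equilibria of the game.

    For each joint strategy pair, the continuous actions are set to the
    closed-form equilibrium of that pair.  With ``deviation="equilibrium"``
    (the default) the scan treats the strategy choice as the stage decision:
    a pair is an equilibrium if no player can lower their cost by switching
    strategy, with the continuous actions re-equilibrating to the deviated
    pair.  With ``deviation="fixed-action"`` the partner's equilibrium action
    is held fixed and the deviating player re-optimizes their own action only
    (a weaker test: strongly coupled costs leave many pairs trivially stable).

    Returns ``[(joint_strategy, (u1, u2), (J1, J2)), ...]``.
    """
    if deviation not in ("equilibrium", "fixed-action"):
        raise ValueError("deviation must be 'equilibrium' or 'fixed-action'")
    cache: dict[tuple, tuple] = {}
    for js in game.joint_strategies():
        try:
            u1, u2 = nash_equilibrium(game, js)
        except np.linalg.LinAlgError:
            continue
        costs = (deterministic_cost(game.spec1, u1, u2, js[0]),
                 deterministic_cost(game.spec2, u2, u1, js[1]))
        cache[js] = ((u1, u2), costs)
    out = []
    for js, (actions, costs) in cache.items():
        stable = True
        for i in range(2):
            for s_alt in game.specs[i].strategies:
                if s_alt == js[i]:
                    continue
                if deviation == "equilibrium":
                    js_alt = (s_alt, js[1]) if i == 0 else (js[0], s_alt)
                    if js_alt not in cache:
                        continue
                    dev = cache[js_alt][1][i]
                else:
                    other_u = actions[1 - i]
                    zeroP = np.zeros((game.specs[i].n_other,
                                      game.specs[i].n_other))
                    dev = expected_cost(game.specs[i], other_u, zeroP, s_alt).q
                if dev < costs[i] - tol:
                    stable = False
                    break
            if not stable:
                break
        if stable:
            out.append((js, actions, costs))
    return out
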