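"""Quadratic-game costs, Nash solutions and the expected-cost decomposition."""

import numpy as np
import pytest

from dyadgames.game_core import (JointGame, PlayerGameSpec, StrategyBlocks,
                                 deterministic_cost, expected_cost,
                                 nash_equilibrium)
from dyadgames.scenario_staghunt import STAG, StagHuntConfig

from conftest import random_spec


def loop_cost(b, u1, u2):
    """Term-by-term scalar-loop expansion of the quadratic cost."""
    total = b.z
    for i in range(len(u1)):
        total += b.r_own[i] * u1[i]
        for j in range(len(u1)):
            total += 0.5 * u1[i] * b.Q_own[i, j] * u1[j]
        for j in range(len(u2)):
            total += u1[i] * b.Q_cross[i, j] * u2[j]
    for i in range(len(u2)):
        total += b.r_other[i] * u2[i]
        for j in range(len(u2)):
            total += 0.5 * u2[i] * b.Q_other[i, j] * u2[j]
    return total


class TestDeterministicCost:
    def test_constant_game(self):
        spec = PlayerGameSpec(1, 1, {"only": StrategyBlocks(
            Q_own=[[1e-6]], Q_cross=[[0.0]], Q_other=[[0.0]],
            r_own=[0.0], r_other=[0.0], z=3.0)})
        # quadratic part negligible at u = 0: pure offset
        assert deterministic_cost(spec, [0.0], [0.0], "only") == 3.0

    def test_lone_stag_hunter_pays_ten(self, staghunt_game):
        cfg = StagHuntConfig()
        assert deterministic_cost(staghunt_game.spec1, [cfg.u_S], [cfg.u_R],
                                  STAG) == pytest.approx(10.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_spec(rng)
        u1, u2 = rng.normal(size=2), rng.normal(size=2)
        for s in spec.strategies:
            assert deterministic_cost(spec, u1, u2, s) == pytest.approx(
                loop_cost(spec.blocks(s), u1, u2), rel=1e-12)

    def test_dimension_mismatch_and_unknown_strategy(self, staghunt_game):
        with pytest.raises(ValueError):
            deterministic_cost(staghunt_game.spec1, [0.0, 1.0], [0.0], STAG)
        with pytest.raises(KeyError):
            deterministic_cost(staghunt_game.spec1, [0.0], [0.0], "wolf")


class TestConstruction:
    def test_indefinite_q_own_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            PlayerGameSpec(1, 1, {"s": StrategyBlocks(
                Q_own=[[-1.0]], Q_cross=[[0.0]], Q_other=[[0.0]],
                r_own=[0.0], r_other=[0.0])})

    def test_near_singular_q_own_rejected(self):
        with pytest.raises(ValueError, match="near-singular"):
            PlayerGameSpec(2, 1, {"s": StrategyBlocks(
                Q_own=[[1.0, 0.0], [0.0, 1e-14]], Q_cross=[[0.0], [0.0]],
                Q_other=[[0.0]], r_own=[0.0, 0.0], r_other=[0.0])})

    def test_asymmetric_q_own_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            PlayerGameSpec(2, 1, {"s": StrategyBlocks(
                Q_own=[[1.0, 0.5], [0.0, 1.0]], Q_cross=[[0.0], [0.0]],
                Q_other=[[0.0]], r_own=[0.0, 0.0], r_other=[0.0])})

    def test_serialization_round_trip(self, rng):
        spec = random_spec(rng, n_own=3, n_other=2, n_strategies=3)
        clone = PlayerGameSpec.from_dict(spec.to_dict())
        for s, s2 in zip(spec.strategies, clone.strategies):
            b, b2 = spec.blocks(s), clone.blocks(s2)
            np.testing.assert_allclose(b.Q_own, b2.Q_own)
            np.testing.assert_allclose(b.r_own, b2.r_own)
            assert b.z == b2.z


class TestNashEquilibrium:
    def test_unforced_game_equilibrium_at_origin(self):
        spec = PlayerGameSpec(2, 2, {"s": StrategyBlocks(
            Q_own=np.eye(2), Q_cross=np.zeros((2, 2)), Q_other=np.eye(2),
            r_own=np.zeros(2), r_other=np.zeros(2))})
        u1, u2 = nash_equilibrium(JointGame(spec, spec), ("s", "s"))
        np.testing.assert_allclose(u1, 0.0)
        np.testing.assert_allclose(u2, 0.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_agrees_with_best_response_iteration(self, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = random_spec(rng, 2, 2, 1), random_spec(rng, 2, 2, 1)
        game = JointGame(s1, s2)
        js = (s1.strategies[0], s2.strategies[0])
        u1s, u2s = nash_equilibrium(game, js)
        # damped simultaneous best responses as an independent oracle
        u1, u2 = np.zeros(2), np.zeros(2)
        zero = np.zeros((2, 2))
        for _ in range(3000):
            b1 = expected_cost(s1, u2, zero, js[0]).u_star
            b2 = expected_cost(s2, u1, zero, js[1]).u_star
            u1 = 0.5 * u1 + 0.5 * b1
            u2 = 0.5 * u2 + 0.5 * b2
        np.testing.assert_allclose(u1, u1s, atol=1e-8)
        np.testing.assert_allclose(u2, u2s, atol=1e-8)

    def test_equilibrium_is_best_response_fixed_point(self, rng):
        s1, s2 = random_spec(rng, 2, 2, 1), random_spec(rng, 2, 2, 1)
        game = JointGame(s1, s2)
        js = (s1.strategies[0], s2.strategies[0])
        u1s, u2s = nash_equilibrium(game, js)
        zero = np.zeros((2, 2))
        np.testing.assert_allclose(
            expected_cost(s1, u2s, zero, js[0]).u_star, u1s, atol=1e-10)
        np.testing.assert_allclose(
            expected_cost(s2, u1s, zero, js[1]).u_star, u2s, atol=1e-10)

    def test_equilibrium_cost_minimal_along_perturbations(self, rng):
        s1, s2 = random_spec(rng, 2, 2, 1), random_spec(rng, 2, 2, 1)
        game = JointGame(s1, s2)
        js = (s1.strategies[0], s2.strategies[0])
        u1s, u2s = nash_equilibrium(game, js)
        base = deterministic_cost(s1, u1s, u2s, js[0])
        for _ in range(20):
            direction = rng.normal(size=2)
            perturbed = deterministic_cost(s1, u1s + 1e-3 * direction, u2s,
                                           js[0])
            assert perturbed >= base - 1e-12

    def test_singular_stacked_system_raises(self):
        # perfectly counteracting coupling makes the stacked matrix singular
        spec = PlayerGameSpec(1, 1, {"s": StrategyBlocks(
            Q_own=[[1.0]], Q_cross=[[1.0]], Q_other=[[0.0]],
            r_own=[1.0], r_other=[0.0])})
        with pytest.raises(np.linalg.LinAlgError):
            nash_equilibrium(JointGame(spec, spec), ("s", "s"))


class TestExpectedCost:
    def test_degenerate_belief_equals_deterministic(self, rng):
        spec = random_spec(rng)
        x = rng.normal(size=2)
        dec = expected_cost(spec, x, np.zeros((2, 2)), spec.strategies[0])
        for _ in range(5):
            u = rng.normal(size=2)
            assert dec.value(u) == pytest.approx(
                deterministic_cost(spec, u, x, spec.strategies[0]), rel=1e-10)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_spec(rng)
        s = spec.strategies[0]
        x = rng.normal(size=2)
        Asqrt = rng.normal(size=(2, 2))
        P = Asqrt @ Asqrt.T
        dec = expected_cost(spec, x, P, s)
        u = rng.normal(size=2)
        draws = rng.multivariate_normal(x, P, size=100_000)
        b = spec.blocks(s)
        vals = (0.5 * u @ b.Q_own @ u + draws @ b.Q_cross.T @ u
                + 0.5 * np.einsum("ni,ij,nj->n", draws, b.Q_other, draws)
                + b.r_own @ u + draws @ b.r_other + b.z)
        mc, se = vals.mean(), vals.std() / np.sqrt(len(vals))
        assert abs(dec.value(u) - mc) < 3 * se

    def test_decoupled_game_optimum_independent_of_belief(self, rng):
        b = random_spec(rng).blocks("s0")
        spec = PlayerGameSpec(2, 2, {"s": StrategyBlocks(
            Q_own=b.Q_own, Q_cross=np.zeros((2, 2)), Q_other=b.Q_other,
            r_own=b.r_own, r_other=b.r_other, z=b.z)})
        expected = -np.linalg.solve(b.Q_own, b.r_own)
        for _ in range(3):
            x = rng.normal(size=2)
            np.testing.assert_allclose(
                expected_cost(spec, x, np.eye(2), "s").u_star, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_quadratic_expectation_identity(self, seed):
        # E[u'Qu] = x'Qx + tr(QP): the decomposition evaluated at the belief
        # mean must reproduce the analytic expectation exactly
        rng = np.random.default_rng(seed)
        spec = random_spec(rng)
        s = spec.strategies[0]
        b = spec.blocks(s)
        x = rng.normal(size=2)
        Asqrt = rng.normal(size=(2, 2))
        P = Asqrt @ Asqrt.T
        dec = expected_cost(spec, x, P, s)
        u = rng.normal(size=2)
        analytic = (0.5 * u @ b.Q_own @ u + u @ b.Q_cross @ x
                    + 0.5 * (x @ b.Q_other @ x + np.trace(b.Q_other @ P))
                    + b.r_own @ u + b.r_other @ x + b.z)
        assert dec.value(u) == pytest.approx(analytic, abs=1e-10)

    def test_non_psd_belief_rejected(self, rng):
        spec = random_spec(rng)
        with pytest.raises(ValueError):
            expected_cost(spec, [0.0, 0.0], -np.eye(2), spec.strategies[0])
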