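"""2-VP reaching game: spline basis, cost assembly, dynamics, equilibria."""

import numpy as np
import pytest

from dyadgames.game_core import (deterministic_cost, nash_equilibrium,
                                 pure_strategy_equilibria)
from dyadgames.scenario_viapoint import (EARLY, LATE, MIDDLE, ViaPointConfig,
                                         assemble_game, build_basis,
                                         interaction_force, motor_command,
                                         trajectory_from_action)


def direct_cost(cfg, basis, u_own, u_other, s, player):
    """Numerical evaluation of the task cost on sampled trajectories."""
    grid = np.arange(cfg.n_grid) * basis.T / cfg.n_grid
    ti = trajectory_from_action(basis, u_own, cfg.p_start, cfg.p_end, grid)
    to = trajectory_from_action(basis, u_other, cfg.p_start, cfg.p_end, grid)
    F = motor_command(ti, to, cfg.mass, cfg.damping, cfg.stiffness)
    tv = trajectory_from_action(basis, u_own, cfg.p_start, cfg.p_end,
                                [cfg.crossing_times[s] * basis.T])
    vp = cfg.via_point(player)
    j_vp = 0.5 * cfg.w1 * np.sum((tv.pos[0] - vp) ** 2)
    j_run = 0.5 * np.mean(cfg.w2 * np.sum((ti.pos - to.pos) ** 2, axis=1)
                          + cfg.r * np.sum(F ** 2, axis=1))
    return j_vp + j_run


class TestSplineBasis:
    def test_interpolates_all_nodes(self, viapoint_basis, rng):
        u = rng.normal(0, 0.03, viapoint_basis.n_free)
        u0 = viapoint_basis.boundary_values(-0.05, 0.05)
        Bf, Bb = viapoint_basis.sampling_operators(viapoint_basis.free_times)
        assert np.max(np.abs(Bf @ u + Bb @ u0 - u)) < 1e-10
        Bf, Bb = viapoint_basis.sampling_operators(viapoint_basis.bnd_times)
        assert np.max(np.abs(Bf @ u + Bb @ u0 - u0)) < 1e-10

    def test_boundary_velocities_vanish(self, viapoint_basis, rng):
        # p(dt) = p(0) and p(T-dt) = p(T) pin the ends; velocity at the
        # extremes must be ~0 relative to mid-movement speed
        u = rng.normal(0, 0.03, viapoint_basis.n_free)
        traj = trajectory_from_action(viapoint_basis,
                                      np.concatenate([u, u]),
                                      (-0.05, 0.0), (0.05, 0.0))
        speed = np.linalg.norm(traj.vel, axis=1)
        assert speed[0] < 0.05 * speed.max()
        assert speed[-1] < 0.05 * speed.max()

    def test_affine_path_reproduced(self, viapoint_basis):
        # free nodes placed on the straight line between the endpoints give
        # back that exact line (the spline reproduces affine functions)
        p0, p1 = -0.05, 0.05
        slope = (p1 - p0) / viapoint_basis.T
        u = p0 + slope * viapoint_basis.free_times
        u0 = np.array([p0, p0 + slope * viapoint_basis.dt,
                       p1 - slope * viapoint_basis.dt, p1])
        times = np.linspace(0, viapoint_basis.T, 57)
        rows_f, rows_b = viapoint_basis.sampling_operators(times)
        vals = rows_f @ u + rows_b @ u0
        np.testing.assert_allclose(vals, p0 + slope * times, atol=1e-9)

    def test_constant_path_has_zero_velocity(self, viapoint_basis):
        u = np.full(viapoint_basis.n_free, 0.02)
        traj = trajectory_from_action(viapoint_basis,
                                      np.concatenate([u, u]),
                                      (0.02, 0.02), (0.02, 0.02))
        np.testing.assert_allclose(traj.pos, 0.02, atol=1e-10)
        np.testing.assert_allclose(traj.vel, 0.0, atol=1e-8)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            build_basis(M=4)

    def test_duplicate_node_times_rejected(self):
        with pytest.raises(ValueError):
            build_basis(M=6, free_times=[0.3, 0.3])


class TestGameAssembly:
    @pytest.mark.parametrize("seed", range(5))
    def test_quadratic_form_matches_direct_evaluation(self, seed,
                                                      viapoint_basis,
                                                      viapoint_game):
        cfg = ViaPointConfig()
        rng = np.random.default_rng(seed)
        for _ in range(10):
            ui = rng.normal(0, 0.03, 10)
            uo = rng.normal(0, 0.03, 10)
            for s in (EARLY, MIDDLE, LATE):
                qf = deterministic_cost(viapoint_game.spec1, ui, uo, s)
                direct = direct_cost(cfg, viapoint_basis, ui, uo, s, 0)
                assert qf == pytest.approx(direct, rel=1e-8)

    def test_own_curvature_blocks_positive_definite(self, viapoint_game):
        for spec in viapoint_game.specs:
            for s in spec.strategies:
                assert np.linalg.eigvalsh(spec.blocks(s).Q_own).min() > 0

    def test_asymmetric_geometry_has_two_ordered_equilibria(self,
                                                            viapoint_game):
        eqs = pure_strategy_equilibria(viapoint_game)
        assert {js for js, _, _ in eqs} == {(EARLY, LATE), (LATE, EARLY)}

    def test_symmetric_equilibria_cost_equivalent(self, viapoint_basis):
        game = assemble_game(ViaPointConfig.symmetric(), viapoint_basis)
        eqs = pure_strategy_equilibria(game)
        assert {js for js, _, _ in eqs} == {(EARLY, LATE), (LATE, EARLY)}
        costs = {js: c for js, _, c in eqs}
        total_el = sum(costs[(EARLY, LATE)])
        total_le = sum(costs[(LATE, EARLY)])
        assert abs(total_el - total_le) < 1e-9

    def test_mirror_symmetry_swaps_equilibria(self, viapoint_basis):
        # reflecting about the start-target axis maps one equilibrium onto
        # the other: player 1's E-cost equals player 2's L-cost, etc.
        game = assemble_game(ViaPointConfig.symmetric(), viapoint_basis)
        costs = {js: c for js, _, c in pure_strategy_equilibria(game)}
        el, le = costs[(EARLY, LATE)], costs[(LATE, EARLY)]
        assert el[0] == pytest.approx(le[1], abs=1e-9)
        assert el[1] == pytest.approx(le[0], abs=1e-9)

    def test_decoupled_game_reduces_to_solo_optima(self, viapoint_basis):
        cfg = ViaPointConfig(w2=0.0, stiffness=0.0)
        game = assemble_game(cfg, viapoint_basis)
        for spec in game.specs:
            for s in spec.strategies:
                np.testing.assert_allclose(spec.blocks(s).Q_cross, 0.0,
                                           atol=1e-9)
        # equilibrium equals each player's independent optimum
        u1, u2 = nash_equilibrium(game, (EARLY, LATE))
        b1 = game.spec1.blocks(EARLY)
        solo1 = -np.linalg.solve(b1.Q_own, b1.r_own)
        np.testing.assert_allclose(u1, solo1, atol=1e-9)


class TestDynamics:
    def test_stationary_coincident_players_no_force(self, viapoint_basis):
        u = np.zeros(10)
        t1 = trajectory_from_action(viapoint_basis, u, (0.0, 0.0), (0.0, 0.0))
        F = motor_command(t1, t1, 1.0, 5.0, 50.0)
        np.testing.assert_allclose(F, 0.0, atol=1e-8)

    def test_unforced_inertia_on_shared_straight_path(self, viapoint_basis):
        # k = b = 0 on an exactly affine path (boundary samples on the same
        # line, so no clamping transient): inertial force vanishes
        from dyadgames.scenario_viapoint import SampledTrajectory
        b = viapoint_basis
        slope = 0.1 / b.T
        u = -0.05 + slope * b.free_times
        u0 = -0.05 + slope * b.bnd_times
        times = np.linspace(0, b.T, 101)
        comps = []
        for deriv in range(3):
            Bf, Bb = b.sampling_operators(times, deriv)
            vals = Bf @ u + Bb @ u0
            comps.append(np.stack([vals, np.zeros_like(vals)], axis=1))
        traj = SampledTrajectory(times=times, pos=comps[0], vel=comps[1],
                                 acc=comps[2])
        F = motor_command(traj, traj, 1.0, 0.0, 0.0)
        assert np.max(np.abs(F)) < 1e-7

    def test_spline_derivatives_match_finite_differences(self, viapoint_basis,
                                                         rng):
        u = rng.normal(0, 0.02, 10)
        grid = np.linspace(0, 1, 2001)
        traj = trajectory_from_action(viapoint_basis, u, (-0.05, 0.0),
                                      (0.05, 0.0), grid)
        h = grid[1] - grid[0]
        fd_vel = np.gradient(traj.pos, h, axis=0)
        interior = slice(5, -5)
        assert np.max(np.abs(fd_vel[interior] - traj.vel[interior])) < \
            50 * h ** 2 * np.max(np.abs(traj.acc))

    def test_interaction_force_antisymmetric_and_linear(self, viapoint_basis,
                                                        rng):
        u1 = rng.normal(0, 0.02, 10)
        u2 = rng.normal(0, 0.02, 10)
        t1 = trajectory_from_action(viapoint_basis, u1, (-0.05, 0.0),
                                    (0.05, 0.0))
        t2 = trajectory_from_action(viapoint_basis, u2, (-0.05, 0.0),
                                    (0.05, 0.0))
        f1 = interaction_force(t1, t2, 50.0)
        f2 = interaction_force(t2, t1, 50.0)
        np.testing.assert_allclose(f1, -f2, atol=1e-12)
        np.testing.assert_allclose(interaction_force(t1, t2, 100.0), 2 * f1,
                                   atol=1e-12)
        np.testing.assert_allclose(interaction_force(t1, t1, 50.0), 0.0)

    def test_grid_mismatch_rejected(self, viapoint_basis, rng):
        u = rng.normal(0, 0.02, 10)
        t1 = trajectory_from_action(viapoint_basis, u, (-0.05, 0.0),
                                    (0.05, 0.0), np.linspace(0, 1, 50))
        t2 = trajectory_from_action(viapoint_basis, u, (-0.05, 0.0),
                                    (0.05, 0.0), np.linspace(0, 1, 60))
        with pytest.raises(ValueError):
            motor_command(t1, t2, 1.0, 5.0, 50.0)
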