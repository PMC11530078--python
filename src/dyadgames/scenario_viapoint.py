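"""Two via-point (2-VP) reaching game.

Two players, mechanically coupled by a virtual spring, reach from a shared
start to a shared target in the plane while each crosses their own via-point
(VP), invisible to the partner.  Per trial, player ``i``'s cost is

    J_i = w1/2 ||p_i(tau_i(s)) - VP_i||^2
          + 1/(2T) * sum_tau [ w2 ||p_i(tau) - p_-i(tau)||^2 + r ||F_i(tau)||^2 ]

where ``F_i = m p''_i + b p'_i + k (p_i - p_-i)`` is the motor command under
point-mass hand dynamics with the coupling spring, and the discrete strategy
``s`` picks the via-point crossing time among three fixed fractions of the
movement (early / middle / late).  Weights follow the Bryson rule: each is
the inverse square of the maximum acceptable magnitude of its term.

Actions are low-dimensional: the trajectory is a cubic polyharmonic spline
through M nodes, four of which (positions at 0, dt, T-dt, T) are clamped to
the start/target so movements begin and end at rest; the free node
coordinates (x and y stacked) form the action vector.  All trajectory samples
and derivatives are linear in the action, so each strategy branch of the cost
is an exact quadratic form assembled from sampling matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .game_core import JointGame, PlayerGameSpec, StrategyBlocks

__all__ = ["SplineBasis", "ViaPointConfig", "SampledTrajectory",
           "build_basis", "assemble_game", "trajectory_from_action",
           "motor_command", "interaction_force", "baseline_params",
           "SENSORY_NOISE", "EARLY", "MIDDLE", "LATE"]

EARLY, MIDDLE, LATE = "E", "M", "L"

# Sensory-noise variances (m^2 per spline node coordinate) emulating the
# information conditions: partner cursor visible (PV, mm-scale perception),
# interaction-force vector displayed (VH), haptic-only (H, cm-scale).
SENSORY_NOISE = {"PV": 1e-6, "VH": 1e-4, "H": 1e-3}


@dataclass(frozen=True)
class SplineBasis:
    """Cubic polyharmonic-spline interpolant with clamped boundary block.

    The spline through node times ``t`` has the form
    ``p(tau) = sum_j v_j |tau - t_j|^3 + c1 tau + c0`` with the usual
    orthogonality side conditions.  ``S_free`` / ``S_bnd`` map free node
    values and the fixed boundary block ``u0 = [p(0), p(dt), p(T-dt), p(T)]``
    to the spline coefficient vector, so any sample of position, velocity or
    acceleration is linear in the free action.
    """

    node_times: np.ndarray      # all M node times, sorted
    free_times: np.ndarray      # the M-4 free node times
    bnd_times: np.ndarray       # (0, dt, T-dt, T)
    T: float
    dt: float
    S_free: np.ndarray          # (M+2, M-4)
    S_bnd: np.ndarray           # (M+2, 4)

    @property
    def n_free(self) -> int:
        return self.S_free.shape[1]

    def boundary_values(self, p_start: float, p_end: float) -> np.ndarray:
        """u0 per axis: clamped so velocity vanishes at both ends."""
        return np.array([p_start, p_start, p_end, p_end])

    def _basis_rows(self, times, deriv: int) -> np.ndarray:
        tau = np.atleast_1d(np.asarray(times, dtype=float))
        d = tau[:, None] - self.node_times[None, :]
        if deriv == 0:
            G = np.abs(d) ** 3
            lin = np.stack([tau, np.ones_like(tau)], axis=1)
        elif deriv == 1:
            G = 3.0 * d * np.abs(d)
            lin = np.stack([np.ones_like(tau), np.zeros_like(tau)], axis=1)
        elif deriv == 2:
            G = 6.0 * np.abs(d)
            lin = np.zeros((len(tau), 2))
        else:
            raise ValueError("deriv must be 0, 1 or 2")
        return np.hstack([G, lin])

    def sampling_operators(self, times, deriv: int = 0):
        """(B_free, B_bnd): samples = B_free @ u_free + B_bnd @ u0, per axis."""
        rows = self._basis_rows(times, deriv)
        return rows @ self.S_free, rows @ self.S_bnd


def build_basis(M: int = 9, T: float = 1.0, dt: float = 0.01,
                free_times=None) -> SplineBasis:
    """Construct the spline basis with M nodes over [0, T].

    Four nodes sit at the clamped boundary times (0, dt, T-dt, T); the
    remaining M-4 free nodes are uniform in the interior unless explicit
    ``free_times`` are given.
    """
    if M < 5:
        raise ValueError("need M >= 5: 4 boundary-clamped samples plus at "
                         "least one free node")
    bnd = np.array([0.0, dt, T - dt, T])
    if free_times is None:
        free = np.linspace(0.0, T, M - 2)[1:-1]
    else:
        free = np.sort(np.asarray(free_times, dtype=float))
        if len(free) != M - 4:
            raise ValueError(f"expected {M - 4} free node times, got {len(free)}")
    t_all = np.concatenate([bnd, free])
    order = np.argsort(t_all)
    t_sorted = t_all[order]
    if np.min(np.diff(t_sorted)) <= 0:
        raise ValueError("duplicate node times make the interpolation "
                         "system singular")
    # polyharmonic interpolation system [G P; P' 0] [v; c] = [values; 0]
    G = np.abs(t_sorted[:, None] - t_sorted[None, :]) ** 3
    Pm = np.stack([t_sorted, np.ones_like(t_sorted)], axis=1)
    A = np.zeros((M + 2, M + 2))
    A[:M, :M] = G
    A[:M, M:] = Pm
    A[M:, :M] = Pm.T
    S_full = np.linalg.solve(A, np.eye(M + 2))[:, :M]  # coeffs = S_full @ values
    # columns of S_full follow t_sorted order; split into boundary vs free
    inv = np.empty_like(order)
    inv[order] = np.arange(M)
    S_cols = S_full[:, inv]   # now column j corresponds to t_all[j]
    basis = SplineBasis(node_times=t_sorted, free_times=free, bnd_times=bnd,
                        T=float(T), dt=float(dt),
                        S_free=S_cols[:, 4:], S_bnd=S_cols[:, :4])
    return basis


@dataclass(frozen=True)
class SampledTrajectory:
    """Planar trajectory samples with consistent derivatives."""

    times: np.ndarray
    pos: np.ndarray   # (n, 2)
    vel: np.ndarray
    acc: np.ndarray


@dataclass
class ViaPointConfig:
    """Geometry, weights, dynamics and crossing-time strategies of the task.

    Defaults are the asymmetric arrangement: start (-5, 0) cm, target
    (5, 0) cm, VP1 = (-2, -3) cm, VP2 = (2, 3) cm; crossing times
    E/M/L = 0.32/0.5/0.68 of the (normalized) movement time.  Bryson weights
    from r_VP = 2.5 mm, d_max = 2 mm, F_max = 1 N.  Hand dynamics are
    order-of-magnitude arm/manipulandum values; the coupling spring stiffness
    matches a soft haptic rendering.
    """

    p_start: tuple = (-0.05, 0.0)
    p_end: tuple = (0.05, 0.0)
    vp1: tuple = (-0.02, -0.03)
    vp2: tuple = (0.02, 0.03)
    crossing_times: Mapping[str, float] = field(
        default_factory=lambda: {EARLY: 0.32, MIDDLE: 0.5, LATE: 0.68})
    w1: float = 1.0 / 0.0025**2   # via-point weight, r_VP = 2.5 mm
    w2: float = 1.0 / 0.002**2    # inter-player distance weight, d_max = 2 mm
    r: float = 1.0                # effort weight, F_max = 1 N
    mass: float = 1.0             # kg
    damping: float = 5.0          # N s/m
    stiffness: float = 50.0       # N/m (soft coupling spring)
    n_grid: int = 100             # cost-sum samples over [0, T]
    M: int = 9                    # spline nodes

    @classmethod
    def symmetric(cls, **kw) -> "ViaPointConfig":
        """Symmetric arrangement: VPs on the midline, crossing times
        0.38/0.5/0.62; the two equilibria are cost-equivalent."""
        kw.setdefault("vp1", (0.0, -0.03))
        kw.setdefault("vp2", (0.0, 0.03))
        kw.setdefault("crossing_times", {EARLY: 0.38, MIDDLE: 0.5, LATE: 0.62})
        return cls(**kw)

    def via_point(self, player: int) -> np.ndarray:
        return np.asarray(self.vp1 if player == 0 else self.vp2, dtype=float)


def _axis_operators(config: ViaPointConfig, basis: SplineBasis):
    """Sampling operators on the cost grid, per derivative order."""
    grid = np.arange(config.n_grid) * basis.T / config.n_grid
    ops = {d: basis.sampling_operators(grid, deriv=d) for d in range(3)}
    return grid, ops


def _stack_axes(B: np.ndarray) -> np.ndarray:
    """Lift a per-axis operator (n x n_free) to the stacked [x; y] action."""
    n, m = B.shape
    out = np.zeros((2 * n, 2 * m))
    out[:n, :m] = B
    out[n:, m:] = B
    return out


def assemble_game(config: ViaPointConfig,
                  basis: SplineBasis | None = None) -> JointGame:
    """Assemble both players' quadratic cost blocks for each strategy.

    Each cost is written as a stacked sum of squares ``J = 1/2 ||E z + e||^2``
    in ``z = [u_own; u_other]`` (via-point rows, inter-player distance rows,
    motor-command rows, each scaled by the square root of its weight), then
    expanded into the standard blocks.
    """
    if basis is None:
        basis = build_basis(M=config.M)
    _, ops = _axis_operators(config, basis)
    nf = basis.n_free
    na = 2 * nf     # stacked action dimension per player
    ngrid = config.n_grid
    u0 = {a: basis.boundary_values(config.p_start[a], config.p_end[a])
          for a in (0, 1)}

    P1, P0 = ops[0]
    V1, V0 = ops[1]
    A1, A0 = ops[2]
    pos1 = _stack_axes(P1)                                    # (2n, na)
    pos0 = np.concatenate([P0 @ u0[0], P0 @ u0[1]])           # (2n,)
    m, b, k = config.mass, config.damping, config.stiffness
    Cown1 = _stack_axes(m * A1 + b * V1 + k * P1)
    Cown0 = np.concatenate([(m * A0 + b * V0) @ u0[0],
                            (m * A0 + b * V0) @ u0[1]])       # spring consts cancel
    sd = np.sqrt(config.w2 / ngrid)
    sf = np.sqrt(config.r / ngrid)

    specs = []
    for player in range(2):
        vp = config.via_point(player)
        blocks = {}
        for s, frac in config.crossing_times.items():
            Gv1, Gv0 = basis.sampling_operators([frac * basis.T], deriv=0)
            vp_rows = np.sqrt(config.w1) * _stack_axes(Gv1)   # (2, na)
            vp_const = np.sqrt(config.w1) * np.array(
                [float((Gv0 @ u0[0])[0]) - vp[0],
                 float((Gv0 @ u0[1])[0]) - vp[1]])
            # rows over z = [u_own, u_other]
            E_own = np.vstack([vp_rows, sd * pos1, sf * Cown1])
            E_oth = np.vstack([np.zeros_like(vp_rows), -sd * pos1,
                               -sf * k * pos1])
            e = np.concatenate([vp_const, np.zeros(2 * ngrid), sf * Cown0])
            blocks[s] = StrategyBlocks(
                Q_own=E_own.T @ E_own, Q_cross=E_own.T @ E_oth,
                Q_other=E_oth.T @ E_oth,
                r_own=E_own.T @ e, r_other=E_oth.T @ e,
                z=0.5 * float(e @ e))
        specs.append(PlayerGameSpec(na, na, blocks))
    return JointGame(specs[0], specs[1])


def baseline_params(condition: str = "PV"):
    """Baseline player parameters per information condition.

    The temperature starts at 1.0 (cost units; costs at play are O(1-100))
    and anneals at 0.99 per trial so exploration fades over a ~100-trial
    training phase; the partner prior is near-deterministic at the workspace
    midline (mu = 0) and believed stationary (A = 0.99, tiny internal noise).
    """
    from .partner_model import PlayerParams
    if condition not in SENSORY_NOISE:
        raise ValueError(f"condition must be one of {sorted(SENSORY_NOISE)}")
    return PlayerParams(sigma_y=SENSORY_NOISE[condition], mu=0.0, p0=1e-6,
                        retention=0.99, sigma_x=1e-6, lambda1=1.0,
                        decay=0.99)


def trajectory_from_action(basis: SplineBasis, u, p_start, p_end,
                           times=None) -> SampledTrajectory:
    """Reconstruct the continuous trajectory encoded by a stacked action.

    ``u`` holds the free node coordinates, x block then y block.  Default
    sampling is 100 Hz over the (normalized 1 s) movement.
    """
    u = np.asarray(u, dtype=float).reshape(-1)
    nf = basis.n_free
    if u.shape[0] != 2 * nf:
        raise ValueError(f"action must have {2 * nf} coordinates (x and y "
                         f"blocks of {nf}), got {u.shape[0]}")
    if times is None:
        times = np.linspace(0.0, basis.T, int(round(100 * basis.T)) + 1)
    times = np.asarray(times, dtype=float)
    out = []
    for deriv in range(3):
        Bf, Bb = basis.sampling_operators(times, deriv=deriv)
        cols = []
        for a in range(2):
            u0 = basis.boundary_values(p_start[a], p_end[a])
            cols.append(Bf @ u[a * nf:(a + 1) * nf] + Bb @ u0)
        out.append(np.stack(cols, axis=1))
    return SampledTrajectory(times=times, pos=out[0], vel=out[1], acc=out[2])


def motor_command(p_own: SampledTrajectory, p_other: SampledTrajectory,
                  mass: float, damping: float, stiffness: float) -> np.ndarray:
    """F_i = m p''_i + b p'_i + k (p_i - p_-i), per sample."""
    if p_own.times.shape != p_other.times.shape or \
            not np.allclose(p_own.times, p_other.times):
        raise ValueError("trajectories must share the same time grid")
    return (mass * p_own.acc + damping * p_own.vel
            + stiffness * (p_own.pos - p_other.pos))


def interaction_force(p_own: SampledTrajectory, p_other: SampledTrajectory,
                      stiffness: float) -> np.ndarray:
    """Spring force rendered on the player: F = -k (p_i - p_-i)."""
    if p_own.times.shape != p_other.times.shape or \
            not np.allclose(p_own.times, p_other.times):
        raise ValueError("trajectories must share the same time grid")
    return -stiffness * (p_own.pos - p_other.pos)
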