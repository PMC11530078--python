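"""Bayesian partner model: trial-by-trial Kalman prediction of partner action.

Each player maintains a Gaussian belief about the partner's next action.  The
prior dynamics assume the partner's action evolves as

    u_-i(t+1) = A u_-i(t) + w,   w ~ N(0, Sigma_x)

(A is a retention/memory rate, Sigma_x the internal or process noise: the
player's belief in how erratic the partner is).  After both players act, a
noisy sensory observation

    y = H u_-i + v,   v ~ N(0, Sigma_y)

is assimilated by the standard Kalman correction, and the retention is applied
to the corrected estimate:

    x' = A { x + K (y - H x) },   P' = A (I - K H) P A' + Sigma_x
    K  = P H' (H P H' + Sigma_y)^-1
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["PlayerParams", "PartnerBelief", "observe", "kalman_gain", "kalman_step"]


def _spherical(v, n: int, name: str) -> np.ndarray:
    """Accept a scalar (interpreted as v*I) or a full n x n matrix."""
    a = np.asarray(v, dtype=float)
    if a.ndim == 0:
        return float(a) * np.eye(n)
    if a.shape != (n, n):
        raise ValueError(f"{name} must be scalar or {n}x{n}, got shape {a.shape}")
    return a


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = 0.5 * (m + m.T)
    if np.linalg.eigvalsh(m)[0] < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")
    return m


@dataclass(frozen=True)
class PlayerParams:
    """The seven behavioral parameters of one player, plus the sensory map H.

    In the spherical-covariance configuration (the default: noises affect all
    action coordinates equally) each of ``sigma_y``, ``p0``, ``sigma_x`` is a
    single variance and ``mu`` a single coordinate value, so the player is
    described by exactly seven free scalars:

    sigma_y   sensory-noise variance (action-units^2); reliability of the
              player's perception of the partner
    mu        prior belief mean about the partner's action (action units)
    p0        prior belief variance
    retention the prior-dynamics memory rate A (dimensionless, 0..1)
    sigma_x   internal/process-noise variance; belief in partner erraticness
    lambda1   initial action-selection temperature (cost units)
    decay     per-trial temperature decay rate a (dimensionless, 0 < a <= 1)

    ``H`` defaults to the identity (the player observes partner action
    coordinates directly).  Any of the covariance-like fields may also be
    given as full matrices.
    """

    sigma_y: float | np.ndarray = 0.1
    mu: float | np.ndarray = 0.0
    p0: float | np.ndarray = 1e-6
    retention: float | np.ndarray = 0.99
    sigma_x: float | np.ndarray = 0.1
    lambda1: float = 0.1
    decay: float = 0.999
    H: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be > 0")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay rate must satisfy 0 < a <= 1")

    FREE_PARAMETER_NAMES = ("sigma_y", "mu", "p0", "retention",
                            "sigma_x", "lambda1", "decay")

    def free_parameters(self) -> dict[str, float]:
        """The seven free scalars of the spherical configuration."""
        out = {}
        for name in self.FREE_PARAMETER_NAMES:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 0:
                raise ValueError(
                    f"{name} is a matrix/vector; the seven-scalar view only "
                    "exists in the spherical configuration")
            out[name] = float(v)
        return out

    # matrix views for a given partner-action dimension -------------------

    def Sigma_y(self, n: int) -> np.ndarray:
        return _check_psd(_spherical(self.sigma_y, n, "sigma_y"), "sigma_y")

    def P0(self, n: int) -> np.ndarray:
        return _check_psd(_spherical(self.p0, n, "p0"), "p0")

    def Sigma_x(self, n: int) -> np.ndarray:
        return _check_psd(_spherical(self.sigma_x, n, "sigma_x"), "sigma_x")

    def A(self, n: int) -> np.ndarray:
        a = np.asarray(self.retention, dtype=float)
        return float(a) * np.eye(n) if a.ndim == 0 else a

    def mu_vec(self, n: int) -> np.ndarray:
        m = np.asarray(self.mu, dtype=float)
        return np.full(n, float(m)) if m.ndim == 0 else m.reshape(n)

    def H_mat(self, n: int) -> np.ndarray:
        return np.eye(n) if self.H is None else np.asarray(self.H, dtype=float)

    def initial_belief(self, n: int) -> "PartnerBelief":
        return PartnerBelief(x=self.mu_vec(n), P=self.P0(n),
                             K=np.zeros((n, self.H_mat(n).shape[0])))

    def replace(self, **kw) -> "PlayerParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PartnerBelief:
    """Gaussian belief about the partner's next action (mean, covariance, last gain)."""

    x: np.ndarray
    P: np.ndarray
    K: np.ndarray


def observe(u_other, H, Sigma_y, rng: np.random.Generator) -> np.ndarray:
    """Noisy sensory observation ``y = H u_other + v``, ``v ~ N(0, Sigma_y)``."""
    u = np.asarray(u_other, dtype=float).reshape(-1)
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != u.shape[0]:
        raise ValueError(f"H has {H.shape[1]} columns but u_other has "
                         f"{u.shape[0]} coordinates")
    Sigma_y = _check_psd(_spherical(Sigma_y, H.shape[0], "Sigma_y"), "Sigma_y")
    mean = H @ u
    if not Sigma_y.any():
        return mean
    # eigh-based square root tolerates semidefinite Sigma_y
    w, V = np.linalg.eigh(Sigma_y)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    return mean + L @ rng.standard_normal(len(mean))


def kalman_gain(P, H, Sigma_y) -> np.ndarray:
    """K = P H' (H P H' + Sigma_y)^-1."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    H = np.atleast_2d(np.asarray(H, dtype=float))
    Sigma_y = _spherical(Sigma_y, H.shape[0], "Sigma_y")
    S = H @ P @ H.T + Sigma_y
    if not S.any():
        if (P @ H.T).any():
            raise np.linalg.LinAlgError("zero innovation covariance with a "
                                        "nonzero prior cross term")
        # deterministic belief observed noiselessly: nothing to correct
        return np.zeros((P.shape[0], H.shape[0]))
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"innovation covariance is singular (cond={cond:.3g})")
    return np.linalg.solve(S.T, (P @ H.T).T).T


def kalman_step(belief: PartnerBelief, y, params: PlayerParams) -> PartnerBelief:
    """One trial-wise belief update; retention applies to the corrected estimate."""
    x = np.asarray(belief.x, dtype=float).reshape(-1)
    n = x.shape[0]
    P = np.atleast_2d(np.asarray(belief.P, dtype=float))
    H = params.H_mat(n)
    A = params.A(n)
    y = np.asarray(y, dtype=float).reshape(-1)
    K = kalman_gain(P, H, params.Sigma_y(H.shape[0]))
    x_new = A @ (x + K @ (y - H @ x))
    P_new = A @ (np.eye(n) - K @ H) @ P @ A.T + params.Sigma_x(n)
    P_new = 0.5 * (P_new + P_new.T)  # numerical hygiene
    return PartnerBelief(x=x_new, P=P_new, K=K)
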