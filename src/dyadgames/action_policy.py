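"""Stochastic action and strategy selection (Boltzmann / quantal response).

Given the Gaussian partner belief (x, P) and a temperature lambda, the joint
density of strategy and action is Boltzmann in the expected cost,

    p(u, s | x) ∝ exp(-E{J(u, u_-i, s)} / lambda).

With positive-definite own-curvature blocks this factorizes exactly: the
action given a strategy is Gaussian, u | s ~ N(u*(s, x), lambda Q_own(s)^-1),
and the strategy probabilities are

    Pr(s | x) ∝ |Q_own(s)|^(-1/2) exp(-q(s, x, P) / lambda),

where q is the residual of the expected-cost decomposition (it carries the
partner-uncertainty term trace(Q_other P)/2, so more partner uncertainty can
shift the strategy choice).  The action distribution is a Gaussian mixture;
its covariance per branch scales with the temperature, so variability
concentrates along low-curvature (task-irrelevant) directions — the minimum
intervention principle falls out of the construction.

The temperature anneals geometrically across trials, lambda(t+1) = a lambda(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

from .game_core import PlayerGameSpec, expected_cost

__all__ = ["PolicyState", "strategy_probabilities", "sample_action",
           "decay_temperature", "LAMBDA_FLOOR"]

# floor keeps densities proper in arbitrarily long annealed runs
LAMBDA_FLOOR = 1e-12


@dataclass(frozen=True)
class PolicyState:
    """Current temperature and trial index of one player's policy."""

    lam: float
    trial_index: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("temperature must be > 0")


def _log_strategy_weights(spec: PlayerGameSpec, x, P, lam: float):
    decomps = [expected_cost(spec, x, P, s) for s in spec.strategies]
    logw = np.empty(len(decomps))
    for j, d in enumerate(decomps):
        sign, logdet = np.linalg.slogdet(d.Q_own)
        logw[j] = -0.5 * logdet - d.q / lam
    return logw, decomps


def strategy_probabilities(spec: PlayerGameSpec, x, P, lam: float) -> np.ndarray:
    """Probability of each strategy of ``spec`` (in ``spec.strategies`` order)."""
    if lam <= 0:
        raise ValueError("temperature must be > 0")
    logw, _ = _log_strategy_weights(spec, x, P, lam)
    return np.exp(logw - logsumexp(logw))


def sample_action(spec: PlayerGameSpec, x, P, lam: float,
                  rng: np.random.Generator) -> tuple[Hashable, np.ndarray]:
    """Draw (strategy, action) from the Boltzmann joint distribution.

    The strategy is drawn from :func:`strategy_probabilities`; the action from
    ``N(u*(s, x), lam * Q_own(s)^-1)`` via the Cholesky factor of ``Q_own``.
    """
    if lam <= 0:
        raise ValueError("temperature must be > 0")
    lam = max(lam, LAMBDA_FLOOR)
    logw, decomps = _log_strategy_weights(spec, x, P, lam)
    probs = np.exp(logw - logsumexp(logw))
    j = int(rng.choice(len(probs), p=probs))
    d = decomps[j]
    # u = u* + sqrt(lam) L^-T xi with Q_own = L L'
    L = np.linalg.cholesky(d.Q_own)
    xi = rng.standard_normal(spec.n_own)
    u = d.u_star + np.sqrt(lam) * solve_triangular(L.T, xi, lower=False)
    return spec.strategies[j], u


def decay_temperature(state: PolicyState, a: float) -> PolicyState:
    """Geometric annealing, applied once per trial: lam' = a * lam."""
    if not (0.0 < a <= 1.0):
        raise ValueError("decay rate must satisfy 0 < a <= 1")
    return PolicyState(lam=max(a * state.lam, LAMBDA_FLOOR),
                       trial_index=state.trial_index + 1)


def mixture_logpdf(spec: PlayerGameSpec, x, P, lam: float, u) -> float:
    """Log density of action ``u`` under the Gaussian-mixture action law."""
    lam = max(lam, LAMBDA_FLOOR)
    logw, decomps = _log_strategy_weights(spec, x, P, lam)
    logpri = logw - logsumexp(logw)
    u = np.asarray(u, dtype=float).reshape(-1)
    d_act = spec.n_own
    comp = np.empty(len(decomps))
    for j, d in enumerate(decomps):
        c, low = cho_factor(d.Q_own)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        diff = u - d.u_star
        maha = diff @ cho_solve((c, low), diff) / lam
        comp[j] = 0.5 * logdet - 0.5 * d_act * np.log(2.0 * np.pi * lam) - 0.5 * maha
    return float(logsumexp(logpri + comp))
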