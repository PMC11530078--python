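"""Per-trial interaction loop: fictitious play with Bayesian partner models.

One trial proceeds in four steps, with strict simultaneous-move semantics
(no within-trial feedback; each player's action only reaches the partner on
the next trial):

1. both players sample (strategy, action) from their current beliefs;
2. each receives a noisy observation of the partner's realized action;
3. each updates their partner belief with one Kalman step;
4. both temperatures decay.

Iterated over a session this is fictitious play: each player best-responds
(stochastically) to a running probabilistic model of the partner.  The engine
doubles as the framework's synthetic-data generator, including the
population protocol of jittering each player's parameters uniformly within a
fraction of baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

import numpy as np

from .action_policy import PolicyState, decay_temperature, sample_action
from .game_core import JointGame, deterministic_cost
from .partner_model import PartnerBelief, PlayerParams, kalman_step, observe

__all__ = ["TrialRecord", "DyadSeries", "run_trial", "run_session",
           "epoch_strategy_probabilities", "jitter_params", "chance_level"]


@dataclass(frozen=True)
class PlayerTrial:
    """One player's slice of a trial record."""

    u: np.ndarray          # realized action
    s: Hashable            # chosen strategy
    y: np.ndarray          # observation of the partner's action
    x: np.ndarray          # belief mean after the update
    P: np.ndarray          # belief covariance after the update
    lam: float             # temperature used on this trial
    cost: float            # realized cost at the played actions


@dataclass(frozen=True)
class TrialRecord:
    t: int
    players: tuple[PlayerTrial, PlayerTrial]


@dataclass
class DyadSeries:
    """Ordered trial records of one simulated dyad, with provenance."""

    records: list[TrialRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.records)

    def actions(self, player: int) -> np.ndarray:
        """(n_trials, n_dim) array of player ``player`` (0/1) actions."""
        return np.array([r.players[player].u for r in self.records])

    def strategies(self, player: int) -> list[Hashable]:
        return [r.players[player].s for r in self.records]

    def joint_strategies(self) -> list[tuple[Hashable, Hashable]]:
        return [(r.players[0].s, r.players[1].s) for r in self.records]


def run_trial(game: JointGame,
              params: Sequence[PlayerParams],
              beliefs: Sequence[PartnerBelief],
              policy_states: Sequence[PolicyState],
              rngs: Sequence[np.random.Generator],
              t: int = 0):
    """Advance the dyad by one trial.

    Returns ``(record, new_beliefs, new_policy_states)``.
    """
    specs = game.specs
    # 1. simultaneous action selection from current beliefs
    chosen = []
    for i in range(2):
        s, u = sample_action(specs[i], beliefs[i].x, beliefs[i].P,
                             policy_states[i].lam, rngs[i])
        chosen.append((s, u))
    # 2. observations of the just-realized partner actions
    obs = []
    for i in range(2):
        other_u = chosen[1 - i][1]
        H = params[i].H_mat(other_u.shape[0])
        obs.append(observe(other_u, H, params[i].Sigma_y(H.shape[0]), rngs[i]))
    # 3. belief updates
    new_beliefs = tuple(kalman_step(beliefs[i], obs[i], params[i])
                        for i in range(2))
    # 4. temperature decay
    new_states = tuple(decay_temperature(policy_states[i], params[i].decay)
                       for i in range(2))
    ptrials = []
    for i in range(2):
        s, u = chosen[i]
        cost = deterministic_cost(specs[i], u, chosen[1 - i][1], s)
        ptrials.append(PlayerTrial(u=u, s=s, y=obs[i], x=new_beliefs[i].x,
                                   P=new_beliefs[i].P,
                                   lam=policy_states[i].lam, cost=cost))
    return TrialRecord(t=t, players=(ptrials[0], ptrials[1])), new_beliefs, new_states


def run_session(game: JointGame,
                params: Sequence[PlayerParams],
                n_trials: int,
                seed: int | np.random.SeedSequence,
                config: Optional[dict] = None) -> DyadSeries:
    """Simulate ``n_trials`` trials of the dyad; reproducible from the seed.

    One RNG stream is derived per player from the session seed, so a player's
    private randomness is unchanged when only the partner's config changes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    child1, child2 = ss.spawn(2)
    rngs = (np.random.default_rng(child1), np.random.default_rng(child2))
    specs = game.specs
    beliefs = tuple(params[i].initial_belief(specs[i].n_other) for i in range(2))
    states = tuple(PolicyState(lam=params[i].lambda1) for i in range(2))
    series = DyadSeries(config=dict(config or {}),
                        seed=ss.entropy if isinstance(ss.entropy, int) else None)
    for t in range(n_trials):
        rec, beliefs, states = run_trial(game, params, beliefs, states, rngs, t=t)
        series.records.append(rec)
    return series


def jitter_params(baseline: PlayerParams, rng: np.random.Generator,
                  fraction: float = 0.1) -> PlayerParams:
    """Population protocol: each of the seven scalars drawn uniformly within
    +/- ``fraction`` of its baseline value."""
    jittered = {}
    for name, v in baseline.free_parameters().items():
        lo, hi = sorted((v * (1 - fraction), v * (1 + fraction)))
        val = float(rng.uniform(lo, hi))
        if name == "decay":
            val = min(val, 1.0)
        if name == "retention":
            val = min(val, 1.0)
        jittered[name] = val
    return baseline.replace(**jittered)


def epoch_strategy_probabilities(series: DyadSeries, epoch_size: int):
    """Per-epoch relative frequencies of each joint strategy pair.

    Trials are grouped into consecutive epochs of ``epoch_size``; a trailing
    partial epoch is dropped.  Returns ``(pairs, probs)`` where ``probs`` has
    one row per epoch (rows sum to 1) and one column per joint pair in
    ``pairs`` (own-spec strategy order).
    """
    if epoch_size < 1:
        raise ValueError("epoch_size must be >= 1")
    joint = series.joint_strategies()
    n_epochs = len(joint) // epoch_size
    pairs = sorted({p for p in joint}, key=str)
    # prefer the full cartesian set when the config snapshot knows the specs
    seen = {p: k for k, p in enumerate(pairs)}
    probs = np.zeros((n_epochs, len(pairs)))
    for e in range(n_epochs):
        block = joint[e * epoch_size:(e + 1) * epoch_size]
        for p in block:
            probs[e, seen[p]] += 1
        probs[e] /= epoch_size
    return pairs, probs


def chance_level(n_options: int = 2) -> float:
    """Probability of any fixed joint strategy under uniform independent play."""
    return 1.0 / (n_options * n_options)
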