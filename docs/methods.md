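# Methods

## Model overview

`dyadgames` simulates and analyzes repeated dyadic sensorimotor games.  Each
trial is simultaneous-move: both players act from their current beliefs, then
each receives one noisy observation of the partner's realized action, updates
a Gaussian partner belief with one Kalman step, and anneals their
action-selection temperature.  No within-trial feedback exists in the model —
one player's action influences the partner only on subsequent trials.  Over
trials the loop is fictitious play: each player (stochastically)
best-responds to a running probabilistic model of the partner's play.

The cost of player *i* is quadratic in both actions with a discrete strategy
picking among cost branches.  Conventions: the ½ multiplies the whole
quadratic bracket and the cross term appears once inside it (so the cost
gradient in `u_i` is `Q_own u_i + Q_cross u_other + r_own`); every
own-curvature block must be symmetric positive definite.  This PD assumption
is what makes the Boltzmann action law a Gaussian mixture and the expected
cost an explicit quadratic; indefinite (competitive) branches are rejected
at construction rather than regularized, because a near-singular or
indefinite curvature would silently invalidate both.  The condition-number
ceiling is 1e12.

Under a Gaussian partner belief `u_other ~ N(x, P)`, the expected cost
completes the square as `½ (u-u*)' Q_own (u-u*) + q(s, x, P)` with
`u* = -Q_own^{-1}(Q_cross x + r_own)` and the residual `q` carrying the
belief-uncertainty penalty `½ trace(Q_other P)`.  That trace term is the
load-bearing piece of the whole framework: it is how distrust of the partner
(large `P`, e.g. from large internal noise `Σx`) penalizes
partner-dependent strategies even when their nominal cost is lower.

## Strategy-level Nash equilibria

`pure_strategy_equilibria` treats the strategy pair as the stage decision:
the continuous actions sit at the closed-form equilibrium of each joint
strategy pair, and a pair is an equilibrium when neither player can lower
their cost by switching strategy with the actions re-equilibrating (the
induced M×M strategy game).  A `deviation="fixed-action"` variant instead
holds the partner's action fixed while the deviating player re-optimizes
their own; it is provided for completeness but is nearly vacuous in strongly
coupled tasks — with the 2-VP Bryson weights, any unilateral path deviation
is so expensive that 7–8 of the 9 strategy pairs are trivially stable under
it.  The induced-game notion is the one that reflects the task's
coordination structure (exactly the two order-consistent equilibria).

## Parameters and defaults

Per player (spherical-covariance configuration; seven free scalars):

| parameter | meaning | units | Stag Hunt default | 2-VP default |
|---|---|---|---|---|
| `sigma_y` | sensory-noise variance | action² | 0.1 / 10 (sweep) | 1e-6 (PV), 1e-4 (VH), 1e-3 (H) m² |
| `mu` | prior belief mean | action | 0 | 0 |
| `p0` | prior belief variance | action² | 1e-6 | 1e-6 |
| `retention` (A) | partner-stationarity memory | — | 0.99 | 0.99 |
| `sigma_x` | internal/process noise | action² | 0.1 / 10 (sweep) | 1e-6 |
| `lambda1` | initial temperature | cost | 0.1 | 1.0 |
| `decay` (a) | temperature decay per trial | — | 0.999 | 0.99 |

`p0 = 1e-6` encodes a near-deterministic prior.  The temperature floor is
1e-12 so densities stay proper in arbitrarily long annealed runs.  The
population protocol for multi-dyad simulations draws each scalar uniformly
within ±10% of baseline, one independent draw per player.

**Stag Hunt geometry.**  The calibration from the corner cost matrix
(rabbit 5, lone stag hunter 10, mutual stag 1) fixes only the spacing
|u_R − u_S| = 2 (giving w = 9/2), not the absolute positions.  We place the
targets symmetrically at u_R = −1, u_S = +1 so that the baseline prior mean
μ = 0 is a neutral midpoint belief.  This matters dynamically: with a
neutral prior the stag branch starts out preferred (expected cost 2.125 vs
5), and the trace penalty `½ w P` flips the preference to the rabbit
exactly when internal noise is high — which is what produces the
convergence map (mutual stag only under low Σx; mutual rabbit otherwise,
regardless of Σy).  Pinning the prior onto one of the targets instead would
hard-wire the outcome and destroy the sweep's structure.  The two algebraic
forms of the stag branch (inter-player coupling vs both-players-at-stag)
agree on all four calibration corners; the coupled form is the simulated
default and the other is available via `literal_cost=True`.

**2-VP geometry and weights.**  Start (−5, 0) cm, target (5, 0) cm;
via-points (−2, −3)/(2, 3) cm asymmetric or (0, ∓3) cm symmetric; crossing
times 0.32/0.5/0.68 T (asymmetric) or 0.38/0.5/0.62 T (symmetric) with
T = 1 normalized.  Bryson-rule weights: w₁ = 1/(2.5 mm)², w₂ = 1/(2 mm)²,
r = 1/(1 N)².  Trajectories are cubic polyharmonic splines with M = 9
nodes: four samples (at 0, Δt, T−Δt, T with Δt = 0.01 s) are clamped to the
endpoints to enforce rest at both ends; the remaining five free nodes are
uniform in the interior, giving a 10-coordinate planar action.  The
running-cost sum uses 100 uniform samples over [0, T], matching a 100 Hz
recording of a 1 s movement; the cost is normalized as ½·mean over samples,
so it is invariant to the grid size.

**Hand dynamics.**  m = 1 kg, b = 5 N·s/m, and coupling stiffness
k = 50 N/m.  These are order-of-magnitude arm/manipulandum values; the
task's haptic rendering was explicitly soft, hence the low stiffness.  The
equilibrium *set* is robust across b ∈ [1, 10] and k ∈ [20, 200] with one
exception: at (b = 5, k = 100) the higher-effort (L, E) equilibrium loses
strategy-level stability to (L, M) by about 0.5% of its cost.  Anyone
changing the dynamics defaults should re-run the equilibrium scan.

## Identification

The analyst observes both players' actions but not a player's internal
belief, which was driven by sensory noise the analyst never sees.  The
belief mean is therefore a latent state with linear-Gaussian dynamics: it
contracts toward the recorded partner action at the player's Kalman-gain
rate and diffuses with variance (A·K_t)²·Σy per trial.  The likelihood of
the observed own actions marginalizes this latent state with a conditional
(Rao-Blackwellized) Kalman filter: per trial, the own action is scored
under the strategy mixture of Gaussians whose means are affine in the
latent belief, and the mixture posterior is collapsed back to a single
Gaussian by moment matching (the only approximation; everything else is
exact).  Each observed own action thereby also serves as a measurement of
the belief that produced it.  A mean-propagation plug-in likelihood
(`conditional=False`) is kept for reference; it ignores the diffusion and
the own-action evidence and substantially understates predictive fit when
sensory noise is large.

Optimization is multi-start L-BFGS-B in a transformed space — log for the
three variances and the temperature, logistic for A ∈ [0, 1] and for
a ∈ [0.9, 1) — so every iterate respects the bounds.  λ₁ is bounded in
[1e-6, 1e3].  The first restart starts from moment-based values (data
variances for the noise scales); the rest are randomized from a seeded
generator, so fits are reproducible.  Constant series are reported as
degenerate (persistent-excitation failure) instead of being fitted.

Predicted actions for R² are the mixture means with posterior strategy
responsibilities — the estimated action series given the identified
strategy sequence, with the belief conditioned on actions up to the
previous trial.  R² is computed per coordinate and averaged, skipping
constant coordinates.  A strict one-step-ahead variant (prior strategy
weights) is available via `predicted_actions(..., own_actions=None)` or the
`prior_weights` flag.

**What recovery studies show.**  On simulated Stag Hunt dyads in the
identifiable regime (Σx = 0.1, Σy = 10, 2000 trials) the predicted-action
R² is ~0.95–0.98 and the retention rate recovers to a few percent, but the
sensory variance estimate is biased upward by a factor of ~3–6: belief
diffusion (∝ Σy) can absorb part of the action-selection randomness, and
the likelihood rewards that flexibility.  The recovery test therefore holds
Σy only to order of magnitude there.  On simulated 2-VP dyads the bias is
mild and Σ̂y tracks the generating value across three orders of magnitude,
which is what the group-ordering check (H > VH > PV) relies on.

## What the synthetic data does and does not emulate

The simulated 2-VP "recordings" are spline-smooth trajectories sampled at
100 Hz from the model's own action representation, with the interaction
force computed from the rendered spring.  They share the real recordings'
format and coordination structure (via-point distances shrink as sensory
noise falls; leader/follower sign structure of the interaction-force power)
but contain no measurement noise, no within-trial corrections, and no
kinematic variability beyond the model's action noise — so passing the
metrics tests shows the pipeline and the model's qualitative predictions,
not that the model fits human data.  The Savitzky-Golay preprocessing
(4th order, 370 ms window) is provided for real recordings; simulated
trajectories do not need it.

## Numerical choices

* Belief covariances are symmetrized after every update; PSD is asserted to
  −1e-10 in tests.
* A zero innovation covariance with a deterministic prior returns gain 0
  (nothing to correct); a singular one otherwise raises.
* Strategy probabilities use log-sum-exp; ties at zero temperature break by
  first-listed strategy.
* Gaussian action sampling uses the Cholesky factor of Q_own.
* Series CSVs are written with `%.17g` and read with round-trip float
  parsing, so write→read is bit-exact.
* The conditional-filter forward pass is JIT-compiled with numba when
  available (pure-float and numpy fallbacks otherwise produce identical
  results to ~1e-13).

## Problem sizes used in the shipped checks

Simulation studies are run at desk scale: the noise-condition convergence
map uses 8 jittered dyads × 500 trials per cell (the qualitative pattern is
established well before trial 500); identification checks fit 2000-trial
Stag Hunt series and 120-trial 2-VP series with 2–5 optimizer restarts.
These sizes were chosen as the smallest at which the respective effects are
stable across seeds.

## Known limitations

* Competitive (indefinite-curvature) games are out of scope by
  construction.
* The strategy-mixture collapse makes the likelihood approximate when
  strategies are persistently ambiguous.
* Σy and λ₁ are partially confounded in 1-D two-strategy tasks (see the
  recovery notes above); fitted Σy values there should be read as ordinal.
* The model has no within-trial feedback, so phenomena that depend on
  mid-movement corrections (e.g. asymmetries between the two via-points'
  leadership indices) are outside its reach.
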