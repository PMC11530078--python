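"""Maximum-likelihood identification of player parameters from action series.

Given the per-trial actions of both players and the (known) cost structure of
one player, the seven behavioral parameters (sigma_y, mu, p0, retention,
sigma_x, lambda1, decay) are estimated by maximizing the likelihood of that
player's observed actions.

The player's internal partner belief is driven by noisy observations the
analyst never sees, so the belief mean x_t is a latent state.  Its dynamics
follow the player's own Kalman recursion driven by the recorded partner
actions,

    x(t+1) = A (I - K_t H) x(t) + A K_t H u_-i(t) + A K_t v(t),

where the gain K_t and belief covariance P_t follow the player's
(data-independent) recursion with sigma_y, and the unobserved sensory noise
v(t) ~ N(0, sigma_y) makes x_t stochastic.  Per trial the observed own
action is scored under the Gaussian-mixture action law

    sum_s Pr(s | x_t, P_t, lam_t) N(u_i(t); u*(s, x_t), lam_t Q_own(s)^-1)

with lam_t = lambda1 * decay^(t-1).  The default likelihood marginalizes the
latent belief with a conditional (Rao-Blackwellized, moment-matched) Kalman
filter over x_t, in which each observed own action also acts as a
measurement of the belief that produced it; the resulting per-trial factors
are exact one-step-ahead predictive densities up to the Gaussian collapse of
the strategy mixture.  A simpler plug-in variant (``conditional=False``)
propagates only the mean of x_t and ignores both the sensory-noise diffusion
and the own-action evidence; it is cheap but systematically underestimates
how well the model predicts when sensory noise is large.

Optimization is multi-start quasi-Newton in a transformed space (log for
variances and temperature, logistic for the two rates), so all restarts
respect the parameter bounds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .action_policy import LAMBDA_FLOOR
from .game_core import PlayerGameSpec
from .partner_model import PlayerParams, kalman_step

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap

__all__ = ["FitResult", "FitConfig", "action_loglik", "fit_player",
           "predicted_actions", "r_squared"]

# decay-rate search window; a approaching 1 keeps exploration alive, values
# below ~0.9 anneal to determinism within tens of trials
DECAY_BOUNDS = (0.9, 1.0 - 1e-9)
LAMBDA1_BOUNDS = (1e-6, 1e3)
VAR_BOUNDS = (1e-10, 1e6)


@dataclass(frozen=True)
class _SpecCache:
    """Per-strategy quantities reused across likelihood evaluations."""

    chol: list          # Cholesky factors of Q_own(s)
    logdet: np.ndarray
    M: list             # u*(s, x) = M_s x + c_s
    c: list
    Q_inv: list
    Q_other: list
    r_other: list
    z: np.ndarray
    tr_other: np.ndarray


def _cache_spec(spec: PlayerGameSpec) -> _SpecCache:
    chol, logdet, M, c, Qi, Qo, ro, z, tr = [], [], [], [], [], [], [], [], []
    for s in spec.strategies:
        b = spec.blocks(s)
        L = np.linalg.cholesky(b.Q_own)
        chol.append(L)
        logdet.append(2.0 * np.sum(np.log(np.diag(L))))
        Minv = np.linalg.inv(b.Q_own)
        Qi.append(Minv)
        M.append(-Minv @ b.Q_cross)
        c.append(-Minv @ b.r_own)
        Qo.append(b.Q_other)
        ro.append(b.r_other)
        z.append(b.z)
        tr.append(np.trace(b.Q_other))
    return _SpecCache(chol=chol, logdet=np.array(logdet), M=M, c=c, Q_inv=Qi,
                      Q_other=Qo, r_other=ro, z=np.array(z),
                      tr_other=np.array(tr))


def _forward_filter(params: PlayerParams, partner_actions: np.ndarray):
    """Belief means and covariances at each trial, driven by y = H u_-i.

    Returns (X, Pvar): X is (n, d) of prior means x_t, Pvar is (n,) of prior
    variances (spherical fast path) or (n, d, d) matrices in the general case.
    """
    Y = np.asarray(partner_actions, dtype=float)
    n, d = Y.shape
    spherical = (params.H is None
                 and np.asarray(params.sigma_y).ndim == 0
                 and np.asarray(params.sigma_x).ndim == 0
                 and np.asarray(params.p0).ndim == 0
                 and np.asarray(params.retention).ndim == 0)
    if spherical:
        sy = float(params.sigma_y)
        sx = float(params.sigma_x)
        A = float(params.retention)
        X = np.empty((n, d))
        Pv = np.empty(n)
        x = params.mu_vec(d)
        P = float(params.p0)
        for t in range(n):
            X[t] = x
            Pv[t] = P
            K = P / (P + sy) if (P + sy) > 0 else 0.0
            x = A * (x + K * (Y[t] - x))
            P = A * A * (1.0 - K) * P + sx
        return X, Pv
    belief = params.initial_belief(d)
    X = np.empty((n, d))
    Pm = np.empty((n, d, d))
    for t in range(n):
        X[t] = belief.x
        Pm[t] = belief.P
        belief = kalman_step(belief, params.H_mat(d) @ Y[t], params)
    return X, Pm


def _mixture_terms(params: PlayerParams, cache: _SpecCache,
                   X: np.ndarray, Pvar) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial per-strategy (log priors, conditional means) and lam_t."""
    n = X.shape[0]
    nS = len(cache.chol)
    t_idx = np.arange(n)
    lam = np.maximum(params.lambda1 * params.decay ** t_idx, LAMBDA_FLOOR)
    logw = np.empty((n, nS))
    means = []
    ptrace = Pvar if np.ndim(Pvar) == 1 else np.einsum("tii->t", Pvar)
    for j in range(nS):
        U = X @ cache.M[j].T + cache.c[j]
        means.append(U)
        if np.ndim(Pvar) == 1:
            tr_term = 0.5 * Pvar * cache.tr_other[j]
        else:
            tr_term = 0.5 * np.einsum("tij,ji->t", Pvar, cache.Q_other[j])
        # q(s, x, P) = z + r_other'x + x'Q_other x/2 + tr(Q_other P)/2
        #              - u*'Q_own u*/2; the last term via the Cholesky factor
        xQx = 0.5 * np.einsum("ti,ij,tj->t", X, cache.Q_other[j], X)
        uLu = 0.5 * np.sum((U @ cache.chol[j]) ** 2, axis=1)
        q = cache.z[j] + X @ cache.r_other[j] + xQx + tr_term - uLu
        logw[:, j] = -0.5 * cache.logdet[j] - q / lam
    logpri = logw - logsumexp(logw, axis=1, keepdims=True)
    return logpri, means, lam


def _scalar_caches(params: PlayerParams, cache: _SpecCache):
    """Flatten per-strategy quantities for the d=1 fast path."""
    nS = len(cache.chol)
    return (np.array([cache.M[j][0, 0] for j in range(nS)]),
            np.array([cache.c[j][0] for j in range(nS)]),
            np.array([cache.Q_inv[j][0, 0] for j in range(nS)]),
            np.array([cache.Q_other[j][0, 0] for j in range(nS)]),
            np.array([cache.r_other[j][0] for j in range(nS)]),
            np.array([1.0 / cache.Q_inv[j][0, 0] for j in range(nS)]))


def _conditional_pass_1d(params: PlayerParams, U: np.ndarray, Y: np.ndarray,
                         cache: _SpecCache, collect: bool,
                         prior_weights: bool):
    """Scalar-action conditional pass in plain floats (hot path)."""
    import math
    n = U.shape[0]
    nS = len(cache.chol)
    Ms_a, cs_a, Qinv_a, Qo_a, ro_a, Qown_a = _scalar_caches(params, cache)
    Ms = Ms_a.tolist(); cs = cs_a.tolist(); Qinv = Qinv_a.tolist()
    Qo = Qo_a.tolist(); ro = ro_a.tolist(); Qown = Qown_a.tolist()
    hld = (0.5 * cache.logdet).tolist()
    zz = cache.z.tolist()
    sy = float(np.asarray(params.sigma_y))
    sx = float(np.asarray(params.sigma_x))
    A = float(np.asarray(params.retention))
    lam1 = float(params.lambda1)
    a_dec = float(params.decay)
    u_all = U[:, 0].tolist()
    y_all = Y[:, 0].tolist()
    m = float(params.mu_vec(1)[0])
    v = 0.0
    P = float(np.asarray(params.p0))
    lam = lam1
    loglik = 0.0
    preds = np.empty((n, 1)) if collect else None
    log2pi = math.log(2.0 * math.pi)
    exp, log = math.exp, math.log
    for t in range(n):
        if lam < LAMBDA_FLOOR:
            lam = LAMBDA_FLOOR
        u = u_all[t]
        ustar = [0.0] * nS
        joint = [0.0] * nS
        logw = [0.0] * nS
        for j in range(nS):
            us = Ms[j] * m + cs[j]
            ustar[j] = us
            q = zz[j] + ro[j] * m + 0.5 * Qo[j] * (m * m + P) \
                - 0.5 * Qown[j] * us * us
            logw[j] = -hld[j] - q / lam
        mx = max(logw)
        lsum = 0.0
        for j in range(nS):
            lsum += exp(logw[j] - mx)
        lnorm = mx + log(lsum)
        for j in range(nS):
            logw[j] -= lnorm
            Svar = Ms[j] * Ms[j] * v + lam * Qinv[j]
            e = u - ustar[j]
            joint[j] = logw[j] - 0.5 * (log2pi + log(Svar)) \
                - 0.5 * e * e / Svar
        mx = max(joint)
        lsum = 0.0
        for j in range(nS):
            lsum += exp(joint[j] - mx)
        ll_t = mx + log(lsum)
        loglik += ll_t
        post = [exp(joint[j] - ll_t) for j in range(nS)]
        if collect:
            w = [exp(lw) for lw in logw] if prior_weights else post
            preds[t, 0] = sum(w[j] * ustar[j] for j in range(nS))
        mc = 0.0
        m_post = [0.0] * nS
        v_post = [0.0] * nS
        for j in range(nS):
            Svar = Ms[j] * Ms[j] * v + lam * Qinv[j]
            gain = Ms[j] * v / Svar
            m_post[j] = m + gain * (u - ustar[j])
            v_post[j] = (1.0 - gain * Ms[j]) * v
            mc += post[j] * m_post[j]
        vc = 0.0
        for j in range(nS):
            dm = m_post[j] - mc
            vc += post[j] * (v_post[j] + dm * dm)
        K = P / (P + sy) if (P + sy) > 0 else 0.0
        a1 = A * (1.0 - K)
        ak = A * K
        m = a1 * mc + ak * y_all[t]
        v = a1 * a1 * vc + ak * ak * sy
        P = A * A * (1.0 - K) * P + sx
        lam *= a_dec
    return loglik, preds


@_njit(cache=True)
def _conditional_core(U_obs, Y, Mst, cst, Qinv, Qown, Qoth, roth, zz, trQo,
                      logdet, lam_all, sy, sx, A, m0, P0, prior_weights):
    """JIT-compiled conditional filter forward pass (any action dimension)."""
    n, d = U_obs.shape
    nS = Mst.shape[0]
    log2pi = np.log(2.0 * np.pi)
    m = m0.copy()
    V = np.zeros((d, d))
    P = P0
    loglik = 0.0
    preds = np.empty((n, d))
    logw = np.empty(nS)
    joint = np.empty(nS)
    ustars = np.empty((nS, d))
    m_posts = np.empty((nS, d))
    V_posts = np.empty((nS, d, d))
    for t in range(n):
        lam = lam_all[t]
        u = U_obs[t]
        for s in range(nS):
            us = Mst[s] @ m + cst[s]
            ustars[s] = us
            q = (zz[s] + roth[s] @ m + 0.5 * m @ (Qoth[s] @ m)
                 + 0.5 * P * trQo[s] - 0.5 * us @ (Qown[s] @ us))
            logw[s] = -0.5 * logdet[s] - q / lam
        mx = logw.max()
        lsum = 0.0
        for s in range(nS):
            lsum += np.exp(logw[s] - mx)
        lnorm = mx + np.log(lsum)
        for s in range(nS):
            logw[s] -= lnorm
            S = Mst[s] @ V @ Mst[s].T + lam * Qinv[s]
            S = 0.5 * (S + S.T)
            L = np.linalg.cholesky(S)
            e = u - ustars[s]
            sol = np.linalg.solve(S, e)
            quad = e @ sol
            logdetS = 0.0
            for i in range(d):
                logdetS += 2.0 * np.log(L[i, i])
            joint[s] = logw[s] - 0.5 * (d * log2pi + logdetS + quad)
            VMt = V @ Mst[s].T
            G = np.linalg.solve(S, VMt.T).T
            m_posts[s] = m + G @ e
            V_posts[s] = V - G @ (Mst[s] @ V)
        mx = joint.max()
        lsum = 0.0
        for s in range(nS):
            lsum += np.exp(joint[s] - mx)
        ll_t = mx + np.log(lsum)
        loglik += ll_t
        post = np.exp(joint - ll_t)
        if prior_weights:
            w = np.exp(logw)
        else:
            w = post
        preds[t] = w @ ustars
        mc = post @ m_posts
        Vc = np.zeros((d, d))
        for s in range(nS):
            dm = m_posts[s] - mc
            Vc += post[s] * (V_posts[s] + np.outer(dm, dm))
        K = P / (P + sy) if (P + sy) > 0 else 0.0
        a1 = A * (1.0 - K)
        ak = A * K
        m = a1 * mc + ak * Y[t]
        V = a1 * a1 * Vc + ak * ak * sy * np.eye(d)
        P = A * A * (1.0 - K) * P + sx
    return loglik, preds


def _conditional_pass(params: PlayerParams, U_obs: np.ndarray, Y: np.ndarray,
                      cache: _SpecCache, collect: bool = False,
                      prior_weights: bool = False):
    """One forward pass of the Rao-Blackwellized conditional filter.

    Tracks a Gaussian over the player's latent belief mean x_t (moments
    m_t, V_t), conditioned on all past own and partner actions; per trial
    the own-action mixture is collapsed back to a single Gaussian with the
    posterior strategy weights.  Returns the summed one-step-ahead log
    density and, when ``collect`` is set, the per-trial mixture action
    means, weighted by the posterior strategy responsibilities (or by the
    prior strategy probabilities when ``prior_weights`` is set, i.e. strict
    one-step-ahead prediction).
    """
    n, d = U_obs.shape
    if d == 1 and not _HAVE_NUMBA:
        return _conditional_pass_1d(params, U_obs, Y, cache, collect,
                                    prior_weights)
    nS = len(cache.chol)
    sy = float(np.asarray(params.sigma_y))
    sx = float(np.asarray(params.sigma_x))
    A = float(np.asarray(params.retention))
    lam_all = np.maximum(
        float(params.lambda1) * float(params.decay) ** np.arange(n),
        LAMBDA_FLOOR)
    # stacked per-strategy arrays for batched linear algebra
    Mst = np.stack(cache.M)                      # (nS, d, d_other)
    cst = np.stack(cache.c)                      # (nS, d)
    Qinv = np.stack(cache.Q_inv)
    Qown = np.stack([L @ L.T for L in cache.chol])
    Qoth = np.stack(cache.Q_other)
    roth = np.stack(cache.r_other)
    if _HAVE_NUMBA:
        ll, preds = _conditional_core(
            np.ascontiguousarray(U_obs), np.ascontiguousarray(Y),
            Mst, cst, Qinv, Qown, Qoth, roth, cache.z, cache.tr_other,
            cache.logdet, lam_all, sy, sx, A, params.mu_vec(d),
            float(np.asarray(params.p0)), bool(prior_weights))
        return float(ll), (preds if collect else None)
    m = params.mu_vec(d)
    V = np.zeros((d, d))
    P = float(np.asarray(params.p0))
    loglik = 0.0
    preds = np.empty((n, d)) if collect else None
    log2pi = np.log(2.0 * np.pi)
    for t in range(n):
        lam = lam_all[t]
        u = U_obs[t]
        ustars = Mst @ m + cst                                   # (nS, d)
        q = (cache.z + roth @ m + 0.5 * m @ Qoth @ m
             + 0.5 * P * cache.tr_other
             - 0.5 * np.einsum("si,sij,sj->s", ustars, Qown, ustars))
        logw = -0.5 * cache.logdet - q / lam
        logw -= logsumexp(logw)
        VMt = V @ Mst.transpose(0, 2, 1)                         # (nS, d, d)
        S = Mst @ VMt + lam * Qinv
        S = 0.5 * (S + S.transpose(0, 2, 1))
        Ls = np.linalg.cholesky(S)
        E = u[None, :] - ustars                                  # (nS, d)
        W = np.linalg.solve(Ls, E[:, :, None])[:, :, 0]
        comp = (-0.5 * d * log2pi
                - np.sum(np.log(np.diagonal(Ls, axis1=1, axis2=2)), axis=1)
                - 0.5 * np.sum(W * W, axis=1))
        joint = logw + comp
        ll_t = logsumexp(joint)
        loglik += ll_t
        post = np.exp(joint - ll_t)
        if collect:
            w = np.exp(logw) if prior_weights else post
            preds[t] = w @ ustars
        G = np.linalg.solve(S, VMt.transpose(0, 2, 1)).transpose(0, 2, 1)
        m_posts = m[None, :] + (G @ E[:, :, None])[:, :, 0]      # (nS, d)
        V_posts = V[None, :, :] - G @ Mst @ V[None, :, :]
        mc = post @ m_posts
        dm = m_posts - mc[None, :]
        Vc = (np.einsum("s,sij->ij", post, V_posts)
              + np.einsum("s,si,sj->ij", post, dm, dm))
        K = P / (P + sy) if (P + sy) > 0 else 0.0
        a1 = A * (1.0 - K)
        m = a1 * mc + A * K * Y[t]
        V = a1 * a1 * Vc + (A * K) ** 2 * sy * np.eye(d)
        P = A * A * (1.0 - K) * P + sx
    return loglik, preds


def _is_spherical(params: PlayerParams) -> bool:
    return (params.H is None
            and all(np.asarray(getattr(params, f)).ndim == 0
                    for f in ("sigma_y", "sigma_x", "p0", "retention")))


def action_loglik(params: PlayerParams, own_actions, partner_actions,
                  spec: PlayerGameSpec, conditional: bool = True) -> float:
    """Summed log-density of the observed own actions under the model.

    ``conditional=True`` (default) marginalizes the latent belief state with
    the conditional filter; ``conditional=False`` uses the mean-propagation
    plug-in likelihood.  Non-spherical parameterizations fall back to the
    plug-in form.
    """
    U_obs = np.atleast_2d(np.asarray(own_actions, dtype=float))
    Y = np.atleast_2d(np.asarray(partner_actions, dtype=float))
    if U_obs.shape[0] != Y.shape[0]:
        raise ValueError("own and partner series must have equal length")
    cache = _cache_spec(spec)
    if conditional and _is_spherical(params):
        ll, _ = _conditional_pass(params, U_obs, Y, cache)
        return float(ll) if np.isfinite(ll) else -1e300
    X, Pvar = _forward_filter(params, Y)
    logpri, means, lam = _mixture_terms(params, cache, X, Pvar)
    d = U_obs.shape[1]
    n, nS = logpri.shape
    comp = np.empty((n, nS))
    for j in range(nS):
        diff = U_obs - means[j]
        maha = np.sum((diff @ cache.chol[j]) ** 2, axis=1) / lam
        comp[:, j] = (0.5 * cache.logdet[j]
                      - 0.5 * d * np.log(2.0 * np.pi * lam) - 0.5 * maha)
    ll = float(np.sum(logsumexp(logpri + comp, axis=1)))
    return ll if np.isfinite(ll) else -1e300


def predicted_actions(params: PlayerParams, partner_actions,
                      spec: PlayerGameSpec, own_actions=None) -> np.ndarray:
    """Per-trial mixture-mean action prediction, sum_s Pr(s|x_t) u*(s, x_t).

    With ``own_actions`` given (and spherical parameters), predictions are
    one-step-ahead means of the conditional filter: the prediction for trial
    t conditions on actions up to t-1 only.  Otherwise the belief is replayed
    open-loop from the partner actions alone.
    """
    Y = np.atleast_2d(np.asarray(partner_actions, dtype=float))
    cache = _cache_spec(spec)
    if own_actions is not None and _is_spherical(params):
        U_obs = np.atleast_2d(np.asarray(own_actions, dtype=float))
        _, preds = _conditional_pass(params, U_obs, Y, cache, collect=True)
        return preds
    X, Pvar = _forward_filter(params, Y)
    logpri, means, _ = _mixture_terms(params, cache, X, Pvar)
    pri = np.exp(logpri)
    out = np.zeros_like(means[0])
    for j in range(len(means)):
        out += pri[:, [j]] * means[j]
    return out


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, per coordinate then averaged.

    Coordinates with zero observed variance are skipped; if none vary the
    result is nan (non-identifiable series).
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))
    vals = []
    for j in range(obs.shape[1]):
        ss_tot = np.sum((obs[:, j] - np.mean(obs[:, j])) ** 2)
        if ss_tot <= 0:
            continue
        ss_res = np.sum((obs[:, j] - pred[:, j]) ** 2)
        vals.append(1.0 - ss_res / ss_tot)
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class FitConfig:
    """Multi-start optimization settings for :func:`fit_player`."""

    n_restarts: int = 10
    seed: int = 0
    maxiter: int = 300
    maxfun: int = 4000
    min_trials: int = 20
    mu_scale: Optional[float] = None   # initial-guess scale for mu; data std if None


@dataclass
class FitResult:
    params: Optional[PlayerParams]
    loglik: float
    predicted: Optional[np.ndarray]
    r2: float
    converged: bool
    degenerate: bool = False
    n_restarts: int = 0
    restart_logliks: list = field(default_factory=list)
    message: str = ""


def _pack(p: PlayerParams) -> np.ndarray:
    a01 = (float(p.decay) - DECAY_BOUNDS[0]) / (DECAY_BOUNDS[1] - DECAY_BOUNDS[0])
    return np.array([
        np.log(float(p.sigma_y)), float(p.mu), np.log(float(p.p0)),
        logit(np.clip(float(p.retention), 1e-9, 1 - 1e-9)),
        np.log(float(p.sigma_x)), np.log(float(p.lambda1)),
        logit(np.clip(a01, 1e-9, 1 - 1e-9))])


def _bounded_exp(x: float, lo: float, hi: float) -> float:
    return float(np.exp(np.clip(x, np.log(lo), np.log(hi))))


def _unpack(theta: np.ndarray) -> PlayerParams:
    lo, hi = DECAY_BOUNDS
    return PlayerParams(
        sigma_y=_bounded_exp(theta[0], *VAR_BOUNDS),
        mu=float(theta[1]),
        p0=_bounded_exp(theta[2], *VAR_BOUNDS),
        retention=float(expit(theta[3])),
        sigma_x=_bounded_exp(theta[4], *VAR_BOUNDS),
        lambda1=_bounded_exp(theta[5], *LAMBDA1_BOUNDS),
        decay=float(lo + (hi - lo) * expit(theta[6])))


def fit_player(own_actions, partner_actions, spec: PlayerGameSpec,
               fit_config: Optional[FitConfig] = None) -> FitResult:
    """Estimate one player's seven parameters by multi-start ML.

    Returns the best restart.  Series without variation (persistent
    excitation failure) are reported as degenerate rather than fitted.
    """
    cfg = fit_config or FitConfig()
    U = np.atleast_2d(np.asarray(own_actions, dtype=float))
    Y = np.atleast_2d(np.asarray(partner_actions, dtype=float))
    n = U.shape[0]
    if n < cfg.min_trials:
        raise ValueError(f"need at least {cfg.min_trials} trials, got {n}")
    if float(np.std(U)) < 1e-12 and float(np.std(Y)) < 1e-12:
        return FitResult(params=None, loglik=float("nan"), predicted=None,
                         r2=float("nan"), converged=False, degenerate=True,
                         message="constant action series: persistent "
                                 "excitation condition not satisfied")
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.mu_scale if cfg.mu_scale is not None \
        else max(float(np.std(Y)), 1e-3)
    center = float(np.mean(Y))

    def neg_ll(theta):
        try:
            return -action_loglik(_unpack(theta), U, Y, spec)
        except (np.linalg.LinAlgError, ValueError):
            return 1e300

    var_y = max(float(np.var(Y)), 1e-8)
    var_u = max(float(np.var(U)), 1e-8)
    best = None
    logliks = []
    for restart in range(cfg.n_restarts):
        if restart == 0:
            # moment-based starting point: noise scales from the data
            # variances, mild annealing, stationary-partner prior
            init = PlayerParams(
                sigma_y=var_y, mu=center, p0=var_y, retention=0.95,
                sigma_x=0.1 * var_y,
                lambda1=float(np.clip(0.1 * var_u, *LAMBDA1_BOUNDS)),
                decay=0.995)
        else:
            init = PlayerParams(
                sigma_y=float(np.exp(rng.uniform(np.log(1e-4), np.log(10.0)))),
                mu=float(center + scale * rng.normal()),
                p0=float(np.exp(rng.uniform(np.log(1e-6), np.log(1.0)))),
                retention=float(rng.uniform(0.5, 0.999)),
                sigma_x=float(np.exp(rng.uniform(np.log(1e-4), np.log(10.0)))),
                lambda1=float(np.exp(rng.uniform(np.log(1e-3), np.log(1.0)))),
                decay=float(rng.uniform(0.95, 0.9995)))
        res = minimize(neg_ll, _pack(init), method="L-BFGS-B",
                       options={"maxiter": cfg.maxiter,
                                "maxfun": cfg.maxfun})
        logliks.append(-float(res.fun))
        if best is None or -res.fun > best[0]:
            best = (-float(res.fun), res)
    ll, res = best
    if not np.isfinite(ll):
        return FitResult(params=None, loglik=ll, predicted=None,
                         r2=float("nan"), converged=False,
                         n_restarts=cfg.n_restarts, restart_logliks=logliks,
                         message="all restarts failed")
    params = _unpack(res.x)
    pred = predicted_actions(params, Y, spec, own_actions=U)
    return FitResult(params=params, loglik=ll, predicted=pred,
                     r2=r_squared(U, pred), converged=bool(res.success),
                     n_restarts=cfg.n_restarts, restart_logliks=logliks,
                     message=str(res.message))
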