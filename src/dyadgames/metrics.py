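"""Behavioral metrics of dyadic coordination on sampled trajectories.

Works on planar trajectories sampled at a uniform rate (100 Hz in the task),
whether simulated or recorded: Savitzky-Golay smoothing with consistent
derivatives, minimum via-point distances and their crossing times, per-trial
strategy labels (early / middle / late crossing of the partner's via-point),
dyad-level collaboration labels, a signed leadership index from the
mechanical power of the interaction force, and learner classification from
end-of-training distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["smooth", "min_vp_distance", "classify_strategy", "classify_dyad",
           "leadership_index", "learner_flag", "collaboration_probability",
           "COLLABORATIVE", "CYCLIC", "NON_COLLABORATIVE", "INVALID",
           "DISTANCE_THRESHOLD"]

# spatial threshold for "crossing" a via-point (m)
DISTANCE_THRESHOLD = 0.02

COLLABORATIVE = "collaborative"
CYCLIC = "cyclic"
NON_COLLABORATIVE = "non-collaborative"
INVALID = "invalid"


def smooth(samples: np.ndarray, fs: float = 100.0, window_s: float = 0.37,
           order: int = 4):
    """Savitzky-Golay smoothing with derivatives from the same local fit.

    Parameters
    ----------
    samples : (n, d) position samples at rate ``fs``
    window_s : filter window in seconds (370 ms default); rounded to an odd
        number of samples
    order : local polynomial order

    Returns (position, velocity, acceleration), all (n, d).
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    win = int(round(window_s * fs))
    if win % 2 == 0:
        win += 1
    if win <= order:
        raise ValueError("window too short for the polynomial order")
    if x.shape[0] < win:
        raise ValueError(f"need at least {win} samples for a {window_s*1e3:.0f} ms window")
    dt = 1.0 / fs
    pos = savgol_filter(x, win, order, deriv=0, axis=0)
    vel = savgol_filter(x, win, order, deriv=1, delta=dt, axis=0)
    acc = savgol_filter(x, win, order, deriv=2, delta=dt, axis=0)
    return pos, vel, acc


def min_vp_distance(pos: np.ndarray, vp, times=None) -> tuple[float, float]:
    """Closest approach of a path to a via-point.

    Returns ``(MD, TC)``: the minimum distance over samples and the time of
    its first occurrence (sample index if no time grid is given).
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    vp = np.asarray(vp, dtype=float).reshape(-1)
    d = np.linalg.norm(pos - vp[None, :], axis=1)
    k = int(np.argmin(d))  # argmin takes the first occurrence on ties
    tc = float(k) if times is None else float(np.asarray(times)[k])
    return float(d[k]), tc


def classify_strategy(md_own: float, md_other: float, tc_own: float,
                      tc_other: float,
                      d: float = DISTANCE_THRESHOLD) -> str:
    """Per-trial strategy of one player from via-point distances and times.

    E: crossed both VPs, own first; L: crossed both, own last; M: crossed own
    VP but ignored the partner's.  A player who misses their *own* via-point
    fits none of the three patterns and is labelled ``invalid`` explicitly.
    Thresholds are strict inequalities.
    """
    if md_own >= d:
        return INVALID
    if md_other >= d:
        return MIDDLE_LABEL
    return EARLY_LABEL if tc_own < tc_other else LATE_LABEL


EARLY_LABEL, MIDDLE_LABEL, LATE_LABEL = "E", "M", "L"


def classify_dyad(s1: str, s2: str) -> str:
    """Dyad label for one trial: collaborative iff the players take opposite
    crossing orders (E-L or L-E); cyclic iff they take the same order (E-E or
    L-L); non-collaborative otherwise (at least one player ignores the other
    or misses their own via-point)."""
    pair = {s1, s2}
    if pair == {EARLY_LABEL, LATE_LABEL}:
        return COLLABORATIVE
    if pair == {EARLY_LABEL} or pair == {LATE_LABEL}:
        return CYCLIC
    return NON_COLLABORATIVE


def leadership_index(f_int: np.ndarray, vel: np.ndarray, tc: float,
                     fs: float = 100.0, window_s: float = 0.3,
                     signed_projection: bool = False) -> float:
    """Signed leadership index at one via-point crossing.

    Mean, over the ``window_s`` interval just before the crossing time
    ``tc``, of the mechanical power of the interaction force on the player,
    ``F_int . v``.  Moving against the interaction force (doing negative
    work on oneself, i.e. dragging the partner) gives a negative index —
    a leader; passively complying with the force gives a positive index —
    a follower.

    ``signed_projection=True`` replaces the power by the force magnitude
    signed by the direction of motion, ``sign(F.v) ||F||`` (an alternative
    reading of a force-power index with units of N rather than W).
    """
    f = np.atleast_2d(np.asarray(f_int, dtype=float))
    v = np.atleast_2d(np.asarray(vel, dtype=float))
    if f.shape != v.shape:
        raise ValueError("force and velocity series must align")
    n = f.shape[0]
    k_end = int(round(tc * fs))          # sample of the crossing
    k_start = max(k_end - int(round(window_s * fs)), 0)
    k_end = min(max(k_end, k_start + 1), n)
    power = np.sum(f[k_start:k_end] * v[k_start:k_end], axis=1)
    if signed_projection:
        mag = np.linalg.norm(f[k_start:k_end], axis=1)
        return float(np.mean(np.sign(power) * mag))
    return float(np.mean(power))


def learner_flag(md_other_series: Sequence[float], epoch_size: int = 12,
                 threshold: float = DISTANCE_THRESHOLD) -> bool:
    """True iff the mean distance to the partner's via-point over the final
    full epoch is strictly below the threshold."""
    md = np.asarray(md_other_series, dtype=float)
    n_epochs = len(md) // epoch_size
    if n_epochs < 1:
        raise ValueError("series shorter than one epoch")
    last = md[(n_epochs - 1) * epoch_size:n_epochs * epoch_size]
    return bool(np.mean(last) < threshold)


def collaboration_probability(dyad_labels: Sequence[str],
                              epoch_size: int = 12) -> np.ndarray:
    """Per-epoch relative frequencies of the three dyad labels.

    Returns an (n_epochs, 3) array with columns (collaborative, cyclic,
    non-collaborative); rows sum to 1.  A trailing partial epoch is dropped.
    """
    labels = list(dyad_labels)
    n_epochs = len(labels) // epoch_size
    cols = (COLLABORATIVE, CYCLIC, NON_COLLABORATIVE)
    out = np.zeros((n_epochs, 3))
    for e in range(n_epochs):
        block = labels[e * epoch_size:(e + 1) * epoch_size]
        for lab in block:
            out[e, cols.index(lab)] += 1
        out[e] /= epoch_size
    return out
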