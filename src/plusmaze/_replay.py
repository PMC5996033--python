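"""Fast array-backed replay used by the fitting routines.

Fitting evaluates the set log-likelihood thousands of times, so the recorded
log is first compiled into flat arrays (:class:`SetArrays`) and then replayed
with tight scalar loops.  A key structural fact keeps this cheap: the value
trajectory of a replay depends only on the per-day learning rates (and the
overnight decay), never on ``beta`` or on the decision weights — those enter
only through the decision index and the logistic.  The replay functions here
therefore return per-trial *value differences*; the likelihood over any number
of (weights, beta) candidates is then a vectorized numpy computation.

This module is private; the readable reference path is
:func:`plusmaze.models.replay_log`, and the two are tested against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import combo_index
from .task import TrialRecord


@dataclass
class SetArrays:
    """One set's log flattened into parallel arrays (0-based day indices)."""

    n: int
    n_days: int
    day0: list[int]
    combo_a: list[int]
    combo_b: list[int]
    arm_a: list[int]
    arm_b: list[int]
    odor_a: list[int]
    odor_b: list[int]
    led_a: list[int]
    led_b: list[int]
    chosen_a: list[bool]
    combo_chosen: list[int]
    arm_chosen: list[int]
    odor_chosen: list[int]
    led_chosen: list[int]
    reward: list[int]
    sign: np.ndarray  # +1 where option a was chosen, -1 otherwise
    day0_arr: np.ndarray

    @classmethod
    def from_records(cls, log: Sequence[TrialRecord]) -> "SetArrays":
        n = len(log)
        day0 = [r.day - 1 for r in log]
        chosen_a = [r.chosen == "a" for r in log]
        picked = [r.chosen_option for r in log]
        return cls(
            n=n,
            n_days=log[-1].day if n else 0,
            day0=day0,
            combo_a=[combo_index(r.option_a.arm, r.option_a.odor, r.option_a.led) for r in log],
            combo_b=[combo_index(r.option_b.arm, r.option_b.odor, r.option_b.led) for r in log],
            arm_a=[r.option_a.arm - 1 for r in log],
            arm_b=[r.option_b.arm - 1 for r in log],
            odor_a=[r.option_a.odor - 1 for r in log],
            odor_b=[r.option_b.odor - 1 for r in log],
            led_a=[r.option_a.led - 1 for r in log],
            led_b=[r.option_b.led - 1 for r in log],
            chosen_a=chosen_a,
            combo_chosen=[combo_index(p.arm, p.odor, p.led) for p in picked],
            arm_chosen=[p.arm - 1 for p in picked],
            odor_chosen=[p.odor - 1 for p in picked],
            led_chosen=[p.led - 1 for p in picked],
            reward=[r.reward for r in log],
            sign=np.where([c for c in chosen_a], 1.0, -1.0),
            day0_arr=np.asarray(day0, dtype=np.intp),
        )


def nrl_value_diffs(
    arrs: SetArrays, alphas: Sequence[float], decay: float = 1.0
) -> np.ndarray:
    """Per-trial pre-update NRL decision index V[a] - V[b] along the log."""
    v = [0.0] * 16
    out = np.empty(arrs.n)
    prev_day = 0
    day0, ca, cb = arrs.day0, arrs.combo_a, arrs.combo_b
    cc, rew = arrs.combo_chosen, arrs.reward
    for t in range(arrs.n):
        d = day0[t]
        if d != prev_day:
            if decay != 1.0:
                f = decay ** (d - prev_day)
                v = [x * f for x in v]
            prev_day = d
        out[t] = v[ca[t]] - v[cb[t]]
        a = alphas[d]
        i = cc[t]
        v[i] += a * (rew[t] - v[i])
    return out


def wam_value_diffs(
    arrs: SetArrays, alphas: Sequence[float], decay: float = 1.0
) -> np.ndarray:
    """Per-trial pre-update WAM feature differences, shape (n, 3).

    Columns are (l_a - l_b, o_a - o_b, c_a - c_b); the decision index for any
    weight vector w is the dot product ``diffs @ w``.
    """
    l = [0.0] * 4
    o = [0.0] * 2
    c = [0.0] * 2
    out = np.empty((arrs.n, 3))
    prev_day = 0
    day0 = arrs.day0
    aa, ab = arrs.arm_a, arrs.arm_b
    oa, ob = arrs.odor_a, arrs.odor_b
    la, lb = arrs.led_a, arrs.led_b
    ach, och, lch, rew = arrs.arm_chosen, arrs.odor_chosen, arrs.led_chosen, arrs.reward
    for t in range(arrs.n):
        d = day0[t]
        if d != prev_day:
            if decay != 1.0:
                f = decay ** (d - prev_day)
                l = [x * f for x in l]
                o = [x * f for x in o]
                c = [x * f for x in c]
            prev_day = d
        out[t, 0] = l[aa[t]] - l[ab[t]]
        out[t, 1] = o[oa[t]] - o[ob[t]]
        out[t, 2] = c[la[t]] - c[lb[t]]
        a = alphas[d]
        r = rew[t]
        i = ach[t]
        l[i] += a * (r - l[i])
        i = och[t]
        o[i] += a * (r - o[i])
        i = lch[t]
        c[i] += a * (r - c[i])
    return out


def loglik_from_index(index: np.ndarray, sign: np.ndarray, beta: float) -> float:
    """Total log-likelihood of the observed choices given per-trial indices.

    ``log P(chosen) = -log(1 + exp(-beta * sign * index))``, computed with
    ``logaddexp`` for stability.
    """
    x = beta * sign * index
    return float(-np.logaddexp(0.0, -x).sum())


def per_day_loglik_from_index(
    index: np.ndarray, sign: np.ndarray, day0: np.ndarray, n_days: int, beta: float
) -> np.ndarray:
    """Log-likelihood split by day (0-based day index array)."""
    x = beta * sign * index
    ll = -np.logaddexp(0.0, -x)
    return np.bincount(day0, weights=ll, minlength=n_days)
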