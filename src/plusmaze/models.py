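"""Learning rules and decision rules for the NRL and WAM models.

Two trial-by-trial models of choice in the multidimensional discrimination
task:

* **NRL** (naive reinforcement learning): every (arm, odor, led) feature
  *combination* — 4 x 2 x 2 = 16 states — carries its own value, delta-rule
  updated when chosen: ``V <- V + alpha * (R - V)``.  The decision index for an
  offered pair is the value difference ``V[a] - V[b]``.

* **WAM** (weighted attention model): each *feature* carries its own value
  (4 arm values, 2 odor values, 2 LED-color values), all three chosen features
  updated by the same delta rule.  The decision index is the dimension-weighted
  difference ``w_l*(l_a - l_b) + w_o*(o_a - o_b) + w_c*(c_a - c_b)`` with
  nonnegative weights summing to 1 — the weights quantify attention allocated
  to each dimension.

Both models map the decision index to a choice probability through a logistic
(softmax for two options) with inverse temperature ``beta``: ``P(a) =
1 / (1 + exp(-beta * index))``.  ``beta = 0`` is random choice; large ``beta``
is near-deterministic.

All operations here are pure: updates return new value states, and
:func:`replay_log` walks a recorded log without side effects.  Predictions are
always computed from the pre-trial state; the update applies after feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import ParameterError, InvalidTrialError
from .task import OfferedOption, TrialRecord

BETA_MAX = 30.0
WEIGHT_TOL = 1e-9


def combo_index(arm: int, odor: int, led: int) -> int:
    """Flat index of a feature combination in the 16-entry NRL value table."""
    return (arm - 1) * 4 + (odor - 1) * 2 + (led - 1)


class NRLValues:
    """The NRL value table: one value in [0, 1] per feature combination."""

    __slots__ = ("v",)

    def __init__(self, v: Sequence[float]):
        v = list(v)
        if len(v) != 16:
            raise ParameterError("NRLValues requires exactly 16 entries")
        self.v = v

    @classmethod
    def zeros(cls) -> "NRLValues":
        return cls([0.0] * 16)

    def value(self, option: OfferedOption) -> float:
        return self.v[combo_index(option.arm, option.odor, option.led)]

    def scaled(self, factor: float) -> "NRLValues":
        """Values multiplied by an overnight decay factor in [0, 1]."""
        return NRLValues([x * factor for x in self.v])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.v, dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, NRLValues) and self.v == other.v

    def __repr__(self) -> str:
        return f"NRLValues({self.v!r})"


class WAMValues:
    """The WAM value state: per-feature values for location, odor and LED color."""

    __slots__ = ("l", "o", "c")

    def __init__(self, l: Sequence[float], o: Sequence[float], c: Sequence[float]):
        l, o, c = list(l), list(o), list(c)
        if len(l) != 4 or len(o) != 2 or len(c) != 2:
            raise ParameterError("WAMValues requires 4 location, 2 odor, 2 color entries")
        self.l, self.o, self.c = l, o, c

    @classmethod
    def zeros(cls) -> "WAMValues":
        return cls([0.0] * 4, [0.0] * 2, [0.0] * 2)

    def scaled(self, factor: float) -> "WAMValues":
        return WAMValues(
            [x * factor for x in self.l],
            [x * factor for x in self.o],
            [x * factor for x in self.c],
        )

    def as_array(self) -> np.ndarray:
        """Concatenated (l1..l4, o1, o2, c1, c2) vector."""
        return np.asarray(self.l + self.o + self.c, dtype=float)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WAMValues)
            and self.l == other.l
            and self.o == other.o
            and self.c == other.c
        )

    def __repr__(self) -> str:
        return f"WAMValues(l={self.l!r}, o={self.o!r}, c={self.c!r})"


@dataclass(frozen=True)
class DecisionWeights:
    """Attention weights (location, odor, LED color): nonnegative, summing to 1."""

    w_l: float
    w_o: float
    w_c: float

    def __post_init__(self) -> None:
        if min(self.w_l, self.w_o, self.w_c) < 0:
            raise ParameterError("decision weights must be nonnegative")
        total = self.w_l + self.w_o + self.w_c
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ParameterError(f"decision weights must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_l, self.w_o, self.w_c], dtype=float)


@dataclass(frozen=True)
class DayParams:
    """One day's free parameters: learning rate, plus decision weights for WAM."""

    alpha: float
    weights: DecisionWeights | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class SetParams:
    """All parameters governing one learning set.

    Per-day learning rates (and, for WAM, per-day decision weights) plus a
    single inverse temperature ``beta`` shared by every day of the set.
    """

    day_params: tuple[DayParams, ...]
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "day_params", tuple(self.day_params))
        if not 0.0 <= self.beta <= BETA_MAX:
            raise ParameterError(f"beta must be in [0, {BETA_MAX}], got {self.beta}")

    @property
    def n_days(self) -> int:
        return len(self.day_params)


@dataclass(frozen=True)
class TrialPrediction:
    """Model output for one trial, computed from the pre-trial value state."""

    index: float
    p_choose_a: float
    deterministic_pick: str  # "a", "b" or "tie"


def nrl_update(
    values: NRLValues, chosen: OfferedOption, reward: int, alpha: float
) -> NRLValues:
    """Delta-rule update of the chosen combination's value; all others unchanged."""
    _check_update_args(reward, alpha)
    idx = combo_index(chosen.arm, chosen.odor, chosen.led)
    v = list(values.v)
    v[idx] += alpha * (reward - v[idx])
    return NRLValues(v)


def wam_update(
    values: WAMValues, chosen: OfferedOption, reward: int, alpha: float
) -> WAMValues:
    """Delta-rule update of the three chosen features' values; all others unchanged."""
    _check_update_args(reward, alpha)
    l, o, c = list(values.l), list(values.o), list(values.c)
    l[chosen.arm - 1] += alpha * (reward - l[chosen.arm - 1])
    o[chosen.odor - 1] += alpha * (reward - o[chosen.odor - 1])
    c[chosen.led - 1] += alpha * (reward - c[chosen.led - 1])
    return WAMValues(l, o, c)


def _check_update_args(reward: int, alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if reward not in (0, 1):
        raise ParameterError(f"reward must be 0 or 1, got {reward}")


def nrl_decision_index(
    values: NRLValues, pair: tuple[OfferedOption, OfferedOption]
) -> float:
    """Value difference V[a] - V[b] between the two offered combinations."""
    a, b = pair
    return values.value(a) - values.value(b)


def wam_decision_index(
    values: WAMValues,
    weights: DecisionWeights,
    pair: tuple[OfferedOption, OfferedOption],
) -> float:
    """Attention-weighted difference of the two options' composite value scores."""
    a, b = pair
    return (
        weights.w_l * (values.l[a.arm - 1] - values.l[b.arm - 1])
        + weights.w_o * (values.o[a.odor - 1] - values.o[b.odor - 1])
        + weights.w_c * (values.c[a.led - 1] - values.c[b.led - 1])
    )


def choice_probability(index: float, beta: float) -> float:
    """Logistic choice rule: P(choose a) = 1 / (1 + exp(-beta * index)).

    Numerically stable for large |beta * index|.
    """
    if beta < 0:
        raise ParameterError(f"beta must be nonnegative, got {beta}")
    x = beta * index
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def deterministic_pick(index: float) -> str:
    """Sign of the decision index: 'a' if positive, 'b' if negative, 'tie' at 0.

    Ties (index exactly 0, e.g. on a set's first trial) carry no prediction;
    downstream fit fractions score them 0.5.
    """
    if index > 0:
        return "a"
    if index < 0:
        return "b"
    return "tie"


@dataclass
class ReplayResult:
    """Trial-by-trial predictions and the value trajectory of a replayed log.

    ``trajectory[t]`` holds the value state *after* trial ``t``'s update
    (16 columns for NRL, 8 for WAM: l1..l4, o1, o2, c1, c2).
    """

    predictions: list[TrialPrediction]
    trajectory: np.ndarray
    day_of_trial: np.ndarray  # 1-based day per trial


def replay_log(
    log: Sequence[TrialRecord],
    set_params: SetParams,
    model_kind: Literal["nrl", "wam"],
    decay: float = 1.0,
) -> ReplayResult:
    """Replay one set's log under a model, emitting predictions and values.

    Values start at zero, are updated trial-by-trial with the day's learning
    rate, and carry over day boundaries (scaled by ``decay`` overnight,
    default 1 = no decay).  Each prediction uses the pre-update state and the
    set-level ``beta``; for WAM the day's decision weights apply.

    The log must be a single set's trials in chronological order, with days
    forming a contiguous 1..N range covered by ``set_params.day_params``.
    """
    if model_kind not in ("nrl", "wam"):
        raise ParameterError(f"unknown model_kind {model_kind!r}")
    if not 0.0 <= decay <= 1.0:
        raise ParameterError(f"decay must be in [0, 1], got {decay}")
    if not log:
        raise InvalidTrialError("cannot replay an empty log")
    _check_chronology(log)
    n_days = log[-1].day
    if set_params.n_days < n_days:
        raise ParameterError(
            f"log spans {n_days} days but only {set_params.n_days} day-parameter "
            "entries were supplied"
        )

    values = NRLValues.zeros() if model_kind == "nrl" else WAMValues.zeros()
    predictions: list[TrialPrediction] = []
    trajectory = np.empty((len(log), 16 if model_kind == "nrl" else 8))
    days = np.empty(len(log), dtype=int)
    prev_day = 1
    for t, rec in enumerate(log):
        if rec.day > prev_day:
            if decay != 1.0:
                values = values.scaled(decay ** (rec.day - prev_day))
            prev_day = rec.day
        dp = set_params.day_params[rec.day - 1]
        pair = (rec.option_a, rec.option_b)
        if model_kind == "nrl":
            index = nrl_decision_index(values, pair)
        else:
            if dp.weights is None:
                raise ParameterError(f"day {rec.day}: WAM replay requires weights")
            index = wam_decision_index(values, dp.weights, pair)
        predictions.append(
            TrialPrediction(
                index=index,
                p_choose_a=choice_probability(index, set_params.beta),
                deterministic_pick=deterministic_pick(index),
            )
        )
        picked = rec.chosen_option
        if model_kind == "nrl":
            values = nrl_update(values, picked, rec.reward, dp.alpha)
        else:
            values = wam_update(values, picked, rec.reward, dp.alpha)
        trajectory[t] = values.as_array()
        days[t] = rec.day
    return ReplayResult(predictions=predictions, trajectory=trajectory, day_of_trial=days)


def _check_chronology(log: Sequence[TrialRecord]) -> None:
    label = log[0].set_label
    if log[0].day != 1:
        raise InvalidTrialError("a set's log must start at day 1")
    prev = (0, 0)
    for rec in log:
        if rec.set_label != label:
            raise InvalidTrialError(
                f"log mixes sets {label!r} and {rec.set_label!r}; replay one set at a time"
            )
        key = (rec.day, rec.trial)
        if key <= prev:
            raise InvalidTrialError(
                f"log is not chronological at day {rec.day}, trial {rec.trial}"
            )
        if rec.day > prev[0] + 1:
            raise InvalidTrialError(f"missing day {prev[0] + 1} in log")
        prev = key


def n_free_parameters(model_kind: str, n_days: int) -> int:
    """Number of free parameters a model spends on an ``n_days`` set.

    NRL: one learning rate per day plus the set-level beta.  WAM: per day a
    learning rate and two free decision weights (the third is fixed by the
    simplex constraint), plus beta.  The per-set difference is ``2 * n_days``,
    the parameter-count penalty used in the AIC comparison.
    """
    if model_kind == "nrl":
        return n_days + 1
    if model_kind == "wam":
        return 3 * n_days + 1
    raise ParameterError(f"unknown model_kind {model_kind!r}")
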