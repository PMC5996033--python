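"""Plus-maze set-shifting task: domain types, trial generation and agent simulation.

The task is a four-arm plus maze in which each trial offers the animal a choice
between two arms.  Each offered arm carries one of two odors and one of two LED
colors, so every option is a (arm, odor, led) feature triple and the two options
of a trial always differ on all three dimensions.  Within a learning *set* a
single sensory dimension (odor or LED color; never location) determines reward:
choosing the option that carries the set's correct feature is rewarded,
deterministically.  Animals run 50-100 trials per day; sets change by
intra-dimensional shifts (new odor pair, odor still rules) or extra-dimensional
shifts (odor -> LED or LED -> odor).

This module provides the data types for trials and protocols, the pseudo-random
offered-pair generator, the deterministic reward rule, and a generative
simulator that produces behavioral logs from artificial agents driven by the
learning models in :mod:`plusmaze.models`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .exceptions import InvalidTrialError, ParameterError

ARMS = (1, 2, 3, 4)
#: The 6 unordered arm pairs; offered pairs are drawn uniformly from these.
ARM_PAIRS = tuple(itertools.combinations(ARMS, 2))

SetLabel = Literal["ODOR1", "ODOR2", "LED"]
Dimension = Literal["odor", "led"]
ModelKind = Literal["nrl", "wam"]


@dataclass(frozen=True)
class OfferedOption:
    """One candidate choice: an arm carrying a specific odor and LED color."""

    arm: int
    odor: int
    led: int

    def __post_init__(self) -> None:
        if self.arm not in (1, 2, 3, 4):
            raise InvalidTrialError(f"arm must be in 1..4, got {self.arm}")
        if self.odor not in (1, 2):
            raise InvalidTrialError(f"odor must be in 1..2, got {self.odor}")
        if self.led not in (1, 2):
            raise InvalidTrialError(f"led must be in 1..2, got {self.led}")


@dataclass(frozen=True)
class TrialRecord:
    """One completed maze trial: the offered pair, the choice and its outcome.

    ``day`` and ``trial`` are 1-based; ``chosen`` is ``"a"`` or ``"b"``;
    ``reward`` is 1 iff the chosen option carried the set's correct feature
    (the schedule is deterministic).
    """

    set_label: str
    day: int
    trial: int
    option_a: OfferedOption
    option_b: OfferedOption
    chosen: str
    reward: int

    def __post_init__(self) -> None:
        if self.option_a.arm == self.option_b.arm:
            raise InvalidTrialError("offered options must be on distinct arms")
        if self.option_a.odor == self.option_b.odor:
            raise InvalidTrialError("offered options must carry distinct odors")
        if self.option_a.led == self.option_b.led:
            raise InvalidTrialError("offered options must carry distinct LED colors")
        if self.chosen not in ("a", "b"):
            raise InvalidTrialError(f"chosen must be 'a' or 'b', got {self.chosen!r}")
        if self.reward not in (0, 1):
            raise InvalidTrialError(f"reward must be 0 or 1, got {self.reward}")
        if self.day < 1 or self.trial < 1:
            raise InvalidTrialError("day and trial indices are 1-based")

    @property
    def chosen_option(self) -> OfferedOption:
        return self.option_a if self.chosen == "a" else self.option_b

    @property
    def unchosen_option(self) -> OfferedOption:
        return self.option_b if self.chosen == "a" else self.option_a

    @property
    def correct_arm(self) -> int:
        """Arm of the correct option, recoverable from the deterministic schedule."""
        return (self.chosen_option if self.reward == 1 else self.unchosen_option).arm


@dataclass(frozen=True)
class SetSpec:
    """One learning set: a reward rule plus its day/trial schedule.

    ``relevant_dimension`` is ``"odor"`` or ``"led"``; location is never the
    relevant dimension in this task.  ``odor_pair_id`` tags the physical odor
    pair in use, distinguishing intra-dimensional shifts; feature indices stay
    {1, 2} because values are reset at set boundaries, so pair identity is
    metadata only.
    """

    set_label: str
    relevant_dimension: str
    correct_feature: int
    n_days: int
    trials_per_day: int = 100
    odor_pair_id: int = 1

    def __post_init__(self) -> None:
        if self.relevant_dimension not in ("odor", "led"):
            raise InvalidTrialError(
                "relevant_dimension must be 'odor' or 'led' (location is never "
                f"relevant), got {self.relevant_dimension!r}"
            )
        if self.correct_feature not in (1, 2):
            raise InvalidTrialError("correct_feature must be 1 or 2")
        if self.n_days < 1 or self.trials_per_day < 1:
            raise InvalidTrialError("n_days and trials_per_day must be positive")


@dataclass(frozen=True)
class ExperimentProtocol:
    """An ordered sequence of learning sets for one training group."""

    group: str
    sets: tuple[SetSpec, ...]

    def __post_init__(self) -> None:
        labels = [s.set_label for s in self.sets]
        expected = {"odor_first": ["ODOR1", "ODOR2", "LED"], "led_first": ["LED", "ODOR1"]}
        if self.group not in expected:
            raise InvalidTrialError(f"unknown group {self.group!r}")
        if labels != expected[self.group]:
            raise InvalidTrialError(
                f"group {self.group!r} requires set order {expected[self.group]}, got {labels}"
            )


def odor_first_protocol(
    n_days: Sequence[int] = (5, 2, 13),
    trials_per_day: int = 100,
    correct_features: Sequence[int] = (1, 1, 1),
) -> ExperimentProtocol:
    """Odor-first training: ODOR1 -> ODOR2 (intra-dim shift) -> LED (extra-dim).

    Default day counts follow the observed mean learning times per set
    (about 4-5, 2 and 13 days); 100 daily trials.
    """
    d1, d2, d3 = n_days
    f1, f2, f3 = correct_features
    return ExperimentProtocol(
        group="odor_first",
        sets=(
            SetSpec("ODOR1", "odor", f1, d1, trials_per_day, odor_pair_id=1),
            SetSpec("ODOR2", "odor", f2, d2, trials_per_day, odor_pair_id=2),
            SetSpec("LED", "led", f3, d3, trials_per_day, odor_pair_id=3),
        ),
    )


def led_first_protocol(
    n_days: Sequence[int] = (9, 10),
    trials_per_day: int = 100,
    correct_features: Sequence[int] = (1, 1),
) -> ExperimentProtocol:
    """LED-first training: LED -> ODOR1 (extra-dimensional shift, new odor pair)."""
    d1, d2 = n_days
    f1, f2 = correct_features
    return ExperimentProtocol(
        group="led_first",
        sets=(
            SetSpec("LED", "led", f1, d1, trials_per_day, odor_pair_id=1),
            SetSpec("ODOR1", "odor", f2, d2, trials_per_day, odor_pair_id=2),
        ),
    )


def generate_offered_pair(
    rng: np.random.Generator, set_spec: SetSpec
) -> tuple[OfferedOption, OfferedOption]:
    """Draw one offered pair: two arms, both odors and both LED colors.

    The arm pair is uniform over the 6 unordered pairs; odor labels {1, 2} are
    assigned to the two arms uniformly at random, and LED labels likewise,
    independently.  Draw order (arm pair, odor assignment, LED assignment) is
    fixed so logs are bit-reproducible from a seed.
    """
    arm_a, arm_b = ARM_PAIRS[rng.integers(0, len(ARM_PAIRS))]
    odor_a, odor_b = (1, 2) if rng.random() < 0.5 else (2, 1)
    led_a, led_b = (1, 2) if rng.random() < 0.5 else (2, 1)
    return OfferedOption(arm_a, odor_a, led_a), OfferedOption(arm_b, odor_b, led_b)


def correct_choice(
    pair: tuple[OfferedOption, OfferedOption], set_spec: SetSpec
) -> str:
    """Return ``"a"`` or ``"b"``: which option carries the set's correct feature.

    Exactly one option qualifies because the two options carry distinct
    features on every dimension.
    """
    a, b = pair
    if a.arm == b.arm or a.odor == b.odor or a.led == b.led:
        raise InvalidTrialError("malformed pair: options share a feature")
    feat_a = getattr(a, set_spec.relevant_dimension)
    return "a" if feat_a == set_spec.correct_feature else "b"


def simulate_agent(
    protocol: ExperimentProtocol,
    model_kind: str,
    params: Mapping[str, "SetParams"],
    seed: int,
    decay: float = 1.0,
) -> list[TrialRecord]:
    """Simulate an artificial agent through a full protocol.

    The agent's choices are sampled from the generative model's softmax
    (NRL or WAM); values reset to zero at each set boundary, persist across
    days within a set (optionally scaled by ``decay`` at each day boundary),
    and only the chosen option's values are updated.  Per-trial draw order is
    (arm pair, odor assignment, LED assignment, choice), from a single
    generator seeded with ``seed``, so the log is fully reproducible.

    Parameters
    ----------
    params
        Mapping from set label to :class:`plusmaze.models.SetParams`; for WAM
        every day's params must carry decision weights.
    """
    from .models import (
        NRLValues,
        WAMValues,
        choice_probability,
        nrl_decision_index,
        nrl_update,
        wam_decision_index,
        wam_update,
    )

    if model_kind not in ("nrl", "wam"):
        raise ParameterError(f"unknown model_kind {model_kind!r}")
    if not 0.0 <= decay <= 1.0:
        raise ParameterError(f"decay must be in [0, 1], got {decay}")

    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for spec in protocol.sets:
        try:
            set_params = params[spec.set_label]
        except KeyError:
            raise ParameterError(f"no parameters supplied for set {spec.set_label!r}")
        if len(set_params.day_params) != spec.n_days:
            raise ParameterError(
                f"set {spec.set_label}: {len(set_params.day_params)} day-parameter "
                f"entries for {spec.n_days} days"
            )
        values = NRLValues.zeros() if model_kind == "nrl" else WAMValues.zeros()
        for day in range(1, spec.n_days + 1):
            day_params = set_params.day_params[day - 1]
            if model_kind == "wam" and day_params.weights is None:
                raise ParameterError("WAM simulation requires decision weights per day")
            if day > 1 and decay != 1.0:
                values = values.scaled(decay)
            for trial in range(1, spec.trials_per_day + 1):
                option_a, option_b = generate_offered_pair(rng, spec)
                if model_kind == "nrl":
                    index = nrl_decision_index(values, (option_a, option_b))
                else:
                    index = wam_decision_index(
                        values, day_params.weights, (option_a, option_b)
                    )
                p_a = choice_probability(index, set_params.beta)
                chosen = "a" if rng.random() < p_a else "b"
                correct = correct_choice((option_a, option_b), spec)
                reward = int(chosen == correct)
                picked = option_a if chosen == "a" else option_b
                if model_kind == "nrl":
                    values = nrl_update(values, picked, reward, day_params.alpha)
                else:
                    values = wam_update(values, picked, reward, day_params.alpha)
                records.append(
                    TrialRecord(
                        set_label=spec.set_label,
                        day=day,
                        trial=trial,
                        option_a=option_a,
                        option_b=option_b,
                        chosen=chosen,
                        reward=reward,
                    )
                )
    return records


def split_by_set(records: Iterable[TrialRecord]) -> dict[str, list[TrialRecord]]:
    """Group a multi-set log by set label, preserving chronological order."""
    out: dict[str, list[TrialRecord]] = {}
    for rec in records:
        out.setdefault(rec.set_label, []).append(rec)
    return out
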