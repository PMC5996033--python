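"""Descriptive behavioral analyses: success rates, learning criteria,
choice-by-correct-arm matrices, and weight-dynamics aggregation.

These operations summarize behavioral logs and fitted attention weights the
way the underlying study conventions do: a set counts as learned on the first
day with at least 75% correct choices; each set splits into an *early* and a
*late* stage at the first day reaching 70%; spatial biases show up in a 4x4
matrix of chosen arm against correct arm; and fitted per-day decision weights
are averaged across animals (mean +/- SEM) per set, day and dimension, plus a
long-format per-animal per-stage table ready for repeated-measures ANOVA in
any statistics environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult
from .exceptions import InvalidTrialError, ParameterError
from .task import TrialRecord

DIMENSIONS = ("location", "odor", "led")

LEARNING_CRITERION = 0.75  # daily success rate at which a set counts as learned
STAGE_THRESHOLD = 0.70  # first day at this rate starts the late stage


@dataclass(frozen=True)
class StageLabel:
    """Stage assignment of one training day within a set."""

    set_label: str
    day: int
    stage: str  # "early" or "late"


@dataclass(frozen=True)
class StageSplit:
    """Early/late partition of a set's days by the 70% performance threshold.

    ``first_late_day`` is None (and ``crossed`` False) when the threshold was
    never reached, in which case every day is early.  The split is permanent:
    days after the first crossing stay late even if performance later dips.
    """

    stages: tuple[str, ...]
    first_late_day: int | None

    @property
    def crossed(self) -> bool:
        return self.first_late_day is not None

    def labels(self, set_label: str) -> list[StageLabel]:
        return [
            StageLabel(set_label, day, stage)
            for day, stage in enumerate(self.stages, start=1)
        ]


def daily_success_rate(log: Sequence[TrialRecord]) -> list[float]:
    """Fraction of rewarded trials per day for one set's log, in day order."""
    if not log:
        raise InvalidTrialError("empty log has no success rate")
    rewards: dict[int, list[int]] = {}
    for rec in log:
        rewards.setdefault(rec.day, []).append(rec.reward)
    days = sorted(rewards)
    if days != list(range(1, len(days) + 1)):
        raise InvalidTrialError(f"days are not contiguous from 1: {days}")
    return [sum(rewards[d]) / len(rewards[d]) for d in days]


def criterion_day(
    rates: Sequence[float], threshold: float = LEARNING_CRITERION
) -> int | None:
    """First day (1-based) whose success rate reaches the learning criterion.

    A rate exactly at the threshold qualifies.  Returns None when the
    criterion is never met (some animals never learn the post-shift set).
    """
    for day, rate in enumerate(rates, start=1):
        if rate >= threshold:
            return day
    return None


def stage_split(
    rates: Sequence[float], threshold: float = STAGE_THRESHOLD
) -> StageSplit:
    """Partition a set's days into early/late at the first threshold crossing."""
    first_late = criterion_day(rates, threshold)
    if first_late is None:
        return StageSplit(stages=("early",) * len(rates), first_late_day=None)
    stages = tuple(
        "early" if day < first_late else "late"
        for day in range(1, len(rates) + 1)
    )
    return StageSplit(stages=stages, first_late_day=first_late)


def choice_matrix(day_trials: Sequence[TrialRecord]) -> np.ndarray:
    """4x4 count matrix ``counts[correct_arm - 1, chosen_arm - 1]`` for one day.

    The diagonal holds correct choices; row sums are trials per correct arm.
    The correct arm is recovered from the deterministic reward schedule (the
    chosen arm when rewarded, the offered alternative otherwise).
    """
    counts = np.zeros((4, 4), dtype=int)
    for rec in day_trials:
        counts[rec.correct_arm - 1, rec.chosen_option.arm - 1] += 1
    return counts


def weights_long_table(
    fits_by_animal: Mapping[str, Mapping[str, FitResult]],
) -> pd.DataFrame:
    """Per-animal per-day fitted decision weights in long format.

    Columns: animal, set_label, day, dimension, weight.  All fits must be WAM.
    """
    rows = []
    for animal, fits in fits_by_animal.items():
        for set_label, fit in fits.items():
            if fit.model_kind != "wam":
                raise ParameterError("weight aggregation requires WAM fits")
            for day, dp in enumerate(fit.set_params.day_params, start=1):
                w = dp.weights.as_array()
                for dim, value in zip(DIMENSIONS, w):
                    rows.append((animal, set_label, day, dim, float(value)))
    return pd.DataFrame(
        rows, columns=["animal", "set_label", "day", "dimension", "weight"]
    )


@dataclass(frozen=True)
class WeightAggregate:
    """Cohort summaries of fitted decision weights.

    ``by_day``: per (set, day, dimension) cross-animal mean, SEM and n; rows
    backed by a single animal carry ``flagged=True`` (their SEM is undefined),
    and days with fewer than half the cohort are dropped.  ``by_stage``: the
    long-format per-animal (set, stage, dimension) mean-weight table that a
    repeated-measures ANOVA consumes.
    """

    by_day: pd.DataFrame
    by_stage: pd.DataFrame


def aggregate_weights(
    fits_by_animal: Mapping[str, Mapping[str, FitResult]],
    stages_by_animal: Mapping[str, Mapping[str, StageSplit]] | None = None,
    min_animal_fraction: float = 0.5,
) -> WeightAggregate:
    """Aggregate fitted WAM weights across a cohort.

    Parameters
    ----------
    fits_by_animal
        ``{animal: {set_label: FitResult}}`` with WAM fits.
    stages_by_animal
        ``{animal: {set_label: StageSplit}}`` from each animal's own success
        rates; when omitted the per-stage table is empty.
    min_animal_fraction
        Days covered by fewer than this fraction of the cohort are dropped
        from the per-day aggregate.
    """
    long = weights_long_table(fits_by_animal)
    n_animals = long["animal"].nunique()
    grouped = long.groupby(["set_label", "day", "dimension"], sort=True)["weight"]
    by_day = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    by_day["flagged"] = by_day["n"] == 1
    min_n = int(np.ceil(min_animal_fraction * n_animals))
    by_day = by_day[by_day["n"] >= min_n].reset_index(drop=True)

    stage_rows = []
    if stages_by_animal is not None:
        for animal, by_set in stages_by_animal.items():
            sub = long[long["animal"] == animal]
            for set_label, split in by_set.items():
                stage_of_day = {
                    day: stage for day, stage in enumerate(split.stages, start=1)
                }
                part = sub[sub["set_label"] == set_label].copy()
                part["stage"] = part["day"].map(stage_of_day)
                means = (
                    part.dropna(subset=["stage"])
                    .groupby(["stage", "dimension"], sort=True)["weight"]
                    .mean()
                )
                for (stage, dim), value in means.items():
                    stage_rows.append((animal, set_label, stage, dim, float(value)))
    by_stage = pd.DataFrame(
        stage_rows, columns=["animal", "set_label", "stage", "dimension", "weight"]
    )
    return WeightAggregate(by_day=by_day, by_stage=by_stage)
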