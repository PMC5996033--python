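"""Model comparison: AIC difference, 90/10 within-day cross-validation,
and the deterministic (no-exploration) fit.

Three complementary views of how well NRL and WAM explain a set's behavior:

* **Deterministic fit** — the fraction of a day's observed choices matching
  the *sign* of the model's decision index, ignoring the softmax entirely.
  Ties (index exactly zero) score 0.5.  Under the deterministic reward
  schedule the NRL can only predict correct choices once the correct
  combinations have been rewarded, so its deterministic fit tends to equal
  the day's success rate; the WAM can also predict systematic mistakes.

* **AIC score** — ``ln L_WAM - ln L_NRL - d`` with ``d = 2 N`` the
  parameter-count difference over the ``N`` included days (WAM spends two
  extra free parameters per day).  Only days whose deterministic NRL fit
  exceeds 50% are included.  Positive scores favor WAM.  Note the score is a
  *log-likelihood* difference penalized by the raw parameter-count
  difference, without the conventional factor of 2; it is used as defined.

* **Cross-validation** — per day, parameters are refit using all earlier
  days plus the first 90% of that day's trials (``ceil(0.9 n)``, so the
  training split is never empty), and the held-out last trials are predicted
  by the fitted model's maximum-probability choice (ties 0.5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from .estimation import FitConfig, FitResult, fit_set
from .exceptions import InvalidTrialError, ParameterError
from .models import SetParams, _check_chronology, replay_log
from .task import TrialRecord


@dataclass(frozen=True)
class AICResult:
    """Eq-style AIC comparison over the days passing the NRL-fit filter.

    ``score`` is None when no day passed the filter ("no comparable days").
    """

    score: float | None
    d: int
    n_days_included: int
    included_days: tuple[int, ...]

    @property
    def comparable(self) -> bool:
        return self.n_days_included > 0


@dataclass(frozen=True)
class ComparisonResult:
    """Full per-set comparison of WAM vs NRL."""

    set_label: str
    aic: AICResult
    fit_wam: FitResult
    fit_nrl: FitResult
    cv_fractions: tuple[tuple[float, float], ...]  # per day (wam, nrl)
    deterministic_fits: tuple[tuple[float, float], ...]  # per day (wam, nrl)
    success_rate: tuple[float, ...]  # per day


def _day_slices(log: Sequence[TrialRecord]) -> list[tuple[int, int, int]]:
    """(day, start, stop) spans of each day in a chronological set log."""
    spans = []
    start = 0
    for t in range(1, len(log) + 1):
        if t == len(log) or log[t].day != log[start].day:
            spans.append((log[start].day, start, t))
            start = t
    return spans


def _det_score(predictions, records) -> float:
    """(matches + 0.5 * ties) / n for a block of trials."""
    score = 0.0
    for pred, rec in zip(predictions, records):
        if pred.deterministic_pick == "tie":
            score += 0.5
        elif pred.deterministic_pick == rec.chosen:
            score += 1.0
    return score / len(records)


def deterministic_fit(
    log: Sequence[TrialRecord],
    set_params: SetParams,
    model_kind: Literal["nrl", "wam"],
    day: int,
    decay: float = 1.0,
) -> float:
    """Deterministic-fit fraction for one day of a set's log.

    The whole set is replayed from zero so the values entering ``day`` are
    those accumulated over the preceding days.
    """
    fits = deterministic_fit_per_day(log, set_params, model_kind, decay)
    try:
        return fits[day - 1]
    except IndexError:
        raise InvalidTrialError(f"log has no day {day}")


def deterministic_fit_per_day(
    log: Sequence[TrialRecord],
    set_params: SetParams,
    model_kind: Literal["nrl", "wam"],
    decay: float = 1.0,
) -> list[float]:
    """Deterministic-fit fraction of every day, in day order."""
    if not log:
        raise InvalidTrialError("cannot score an empty log")
    replay = replay_log(log, set_params, model_kind, decay)
    return [
        _det_score(replay.predictions[start:stop], log[start:stop])
        for _, start, stop in _day_slices(log)
    ]


def aic_score(
    fit_wam: FitResult,
    fit_nrl: FitResult,
    deterministic_nrl_fits: Sequence[float],
) -> AICResult:
    """AIC comparison ``ln L_WAM - ln L_NRL - d`` over filtered days.

    Days are included only when the deterministic NRL fit is strictly above
    0.5; ``d = 2 * n_included``.  With no includable day the result is an
    explicit "no comparable days" value (``score=None``), never 0.
    """
    if fit_wam.model_kind != "wam" or fit_nrl.model_kind != "nrl":
        raise ParameterError("aic_score expects (WAM fit, NRL fit) in that order")
    n_days = len(fit_nrl.per_day_ll)
    if len(fit_wam.per_day_ll) != n_days or len(deterministic_nrl_fits) != n_days:
        raise ParameterError("per-day inputs cover different day counts")
    included = tuple(
        d + 1 for d in range(n_days) if deterministic_nrl_fits[d] > 0.5
    )
    if not included:
        return AICResult(score=None, d=0, n_days_included=0, included_days=())
    ll_wam = sum(fit_wam.per_day_ll[d - 1] for d in included)
    ll_nrl = sum(fit_nrl.per_day_ll[d - 1] for d in included)
    d_penalty = 2 * len(included)
    return AICResult(
        score=ll_wam - ll_nrl - d_penalty,
        d=d_penalty,
        n_days_included=len(included),
        included_days=included,
    )


def cross_validate(
    log: Sequence[TrialRecord],
    model_kind: Literal["nrl", "wam"],
    config: FitConfig | None = None,
) -> dict[int, float]:
    """Within-day 90/10 cross-validation; returns {day: test fraction}.

    For each day the model is refit from scratch on the preceding days plus
    the first ``ceil(0.9 n)`` of that day's trials; the day's remaining trials
    are predicted by the maximum-probability choice (equivalently the sign of
    the decision index; ties score 0.5).  Days too short for a nonempty test
    split are skipped with a warning.  Held-out trials never enter fitting.
    """
    config = config or FitConfig()
    _check_chronology(log)
    out: dict[int, float] = {}
    spans = _day_slices(log)
    for day, start, stop in spans:
        n = stop - start
        n_train = math.ceil(0.9 * n)
        n_test = n - n_train
        if n_test == 0:
            warnings.warn(
                f"day {day}: {n} trials leave no test split; day skipped",
                stacklevel=2,
            )
            continue
        train = list(log[: start + n_train])
        fit = fit_set(train, model_kind, config)
        # Replay through the end of the day; held-out predictions still use
        # each trial's pre-trial state, which legitimately includes outcomes
        # of earlier held-out trials as they become history.
        replay = replay_log(list(log[:stop]), fit.set_params, model_kind, config.decay)
        test_preds = replay.predictions[start + n_train : stop]
        test_recs = log[start + n_train : stop]
        out[day] = _det_score(test_preds, test_recs)
    return out


def compare_models(
    log: Sequence[TrialRecord],
    config: FitConfig | None = None,
    run_cv: bool = True,
) -> ComparisonResult:
    """Fit both models to one set's log and compute all comparison metrics."""
    config = config or FitConfig()
    fit_wam = fit_set(log, "wam", config)
    fit_nrl = fit_set(log, "nrl", config)
    det_wam = deterministic_fit_per_day(log, fit_wam.set_params, "wam", config.decay)
    det_nrl = deterministic_fit_per_day(log, fit_nrl.set_params, "nrl", config.decay)
    aic = aic_score(fit_wam, fit_nrl, det_nrl)
    if run_cv:
        cv_wam = cross_validate(log, "wam", config)
        cv_nrl = cross_validate(log, "nrl", config)
        days = sorted(set(cv_wam) & set(cv_nrl))
        cv = tuple((cv_wam[d], cv_nrl[d]) for d in days)
    else:
        cv = ()
    rates = []
    for _, start, stop in _day_slices(log):
        rates.append(sum(r.reward for r in log[start:stop]) / (stop - start))
    return ComparisonResult(
        set_label=log[0].set_label,
        aic=aic,
        fit_wam=fit_wam,
        fit_nrl=fit_nrl,
        cv_fractions=cv,
        deterministic_fits=tuple(zip(det_wam, det_nrl)),
        success_rate=tuple(rates),
    )
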