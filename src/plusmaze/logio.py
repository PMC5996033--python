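"""Readers and writers for behavioral-log CSV files and parameter/result JSON.

The log dialect is plain comma-separated UTF-8 with a mandatory header::

    group,set_label,day,trial,arm_a,odor_a,led_a,arm_b,odor_b,led_b,chosen,reward

One file holds one animal's full log; ``day`` and ``trial`` are 1-based.
Reading validates every row against the trial invariants (distinct arms,
odors and LED colors within a pair), rejects duplicate (set, day, trial) keys
and non-chronological ordering, and reports failures with the offending line
number.  When the experiment's set rules are supplied, reward consistency with
the deterministic schedule is checked too — as a warning by default, since
real apparatus logs can contain delivery errors, or as an error in strict
mode.

Parameters and fit results are serialized as JSON; floats use Python's
shortest round-trip representation, so rereading reproduces values exactly.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

from .estimation import FitResult
from .exceptions import LogValidationError
from .models import DayParams, DecisionWeights, SetParams
from .task import ExperimentProtocol, OfferedOption, SetSpec, TrialRecord, correct_choice

LOG_COLUMNS = (
    "group",
    "set_label",
    "day",
    "trial",
    "arm_a",
    "odor_a",
    "led_a",
    "arm_b",
    "odor_b",
    "led_b",
    "chosen",
    "reward",
)


def write_log(path: str | Path, group: str, records: Iterable[TrialRecord]) -> None:
    """Write one animal's behavioral log in the documented CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for rec in records:
            writer.writerow(
                (
                    group,
                    rec.set_label,
                    rec.day,
                    rec.trial,
                    rec.option_a.arm,
                    rec.option_a.odor,
                    rec.option_a.led,
                    rec.option_b.arm,
                    rec.option_b.odor,
                    rec.option_b.led,
                    rec.chosen,
                    rec.reward,
                )
            )


def read_log(
    path: str | Path,
    sets: Mapping[str, SetSpec] | ExperimentProtocol | None = None,
    strict: bool = False,
) -> tuple[str, list[TrialRecord]]:
    """Read and validate a behavioral log; returns (group, records).

    ``sets`` (a protocol or a set-label mapping) enables reward-consistency
    checking against the deterministic schedule; inconsistencies warn unless
    ``strict`` is set, in which case they raise.
    """
    if isinstance(sets, ExperimentProtocol):
        sets = {s.set_label: s for s in sets.sets}
    path = Path(path)
    records: list[TrialRecord] = []
    group: str | None = None
    seen_sets: list[str] = []
    seen_keys: set[tuple[str, int, int]] = set()
    prev_key: tuple[int, int] | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogValidationError(f"{path}: empty file")
        if tuple(header) != LOG_COLUMNS:
            raise LogValidationError(
                f"{path}: bad header {header!r}; expected {','.join(LOG_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(LOG_COLUMNS):
                raise LogValidationError(
                    f"{path}:{lineno}: expected {len(LOG_COLUMNS)} fields, got {len(row)}"
                )
            try:
                rec = TrialRecord(
                    set_label=row[1],
                    day=int(row[2]),
                    trial=int(row[3]),
                    option_a=OfferedOption(int(row[4]), int(row[5]), int(row[6])),
                    option_b=OfferedOption(int(row[7]), int(row[8]), int(row[9])),
                    chosen=row[10],
                    reward=int(row[11]),
                )
            except (ValueError, TypeError) as exc:
                raise LogValidationError(f"{path}:{lineno}: {exc}") from exc
            if group is None:
                group = row[0]
            elif row[0] != group:
                raise LogValidationError(
                    f"{path}:{lineno}: mixed groups {group!r} and {row[0]!r}"
                )
            key = (rec.set_label, rec.day, rec.trial)
            if key in seen_keys:
                raise LogValidationError(
                    f"{path}:{lineno}: duplicate (set, day, trial) key {key}"
                )
            seen_keys.add(key)
            if not seen_sets or seen_sets[-1] != rec.set_label:
                if rec.set_label in seen_sets:
                    raise LogValidationError(
                        f"{path}:{lineno}: set {rec.set_label!r} reappears after "
                        "another set; sets must be contiguous blocks"
                    )
                seen_sets.append(rec.set_label)
                prev_key = (0, 0)
            if (rec.day, rec.trial) <= prev_key:
                raise LogValidationError(
                    f"{path}:{lineno}: trials out of chronological order "
                    f"(day {rec.day}, trial {rec.trial})"
                )
            prev_key = (rec.day, rec.trial)
            if sets is not None and rec.set_label in sets:
                expected = correct_choice(
                    (rec.option_a, rec.option_b), sets[rec.set_label]
                )
                consistent = rec.reward == int(rec.chosen == expected)
                if not consistent:
                    msg = (
                        f"{path}:{lineno}: reward {rec.reward} inconsistent with "
                        f"the {rec.set_label} rule"
                    )
                    if strict:
                        raise LogValidationError(msg)
                    warnings.warn(msg, stacklevel=2)
            records.append(rec)
    if not records:
        raise LogValidationError(f"{path}: no trial rows")
    return group, records


# ---------------------------------------------------------------------------
# parameter / result JSON


def set_params_to_dict(params: SetParams) -> dict:
    days = []
    for dp in params.day_params:
        entry: dict = {"alpha": dp.alpha}
        if dp.weights is not None:
            entry["weights"] = [dp.weights.w_l, dp.weights.w_o, dp.weights.w_c]
        days.append(entry)
    return {"beta": params.beta, "days": days}


def set_params_from_dict(data: Mapping) -> SetParams:
    days = []
    for entry in data["days"]:
        weights = entry.get("weights")
        days.append(
            DayParams(
                alpha=float(entry["alpha"]),
                weights=None if weights is None else DecisionWeights(*map(float, weights)),
            )
        )
    return SetParams(day_params=tuple(days), beta=float(data["beta"]))


def save_params(path: str | Path, params: Mapping[str, SetParams]) -> None:
    """Write a {set_label: SetParams} mapping as JSON."""
    payload = {label: set_params_to_dict(p) for label, p in params.items()}
    _dump_json(path, payload)


def load_params(path: str | Path) -> dict[str, SetParams]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {label: set_params_from_dict(p) for label, p in payload.items()}


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "set_label": fit.set_label,
        "model_kind": fit.model_kind,
        "params": set_params_to_dict(fit.set_params),
        "log_likelihood": fit.log_likelihood,
        "per_day_ll": list(fit.per_day_ll),
        "converged": fit.converged,
        "n_trials": fit.n_trials,
        "beta_at_bound": fit.beta_at_bound,
    }


def fit_result_from_dict(data: Mapping) -> FitResult:
    return FitResult(
        set_label=data["set_label"],
        model_kind=data["model_kind"],
        set_params=set_params_from_dict(data["params"]),
        log_likelihood=float(data["log_likelihood"]),
        per_day_ll=tuple(float(v) for v in data["per_day_ll"]),
        converged=bool(data["converged"]),
        n_trials=int(data["n_trials"]),
        beta_at_bound=bool(data["beta_at_bound"]),
    )


def save_fit(path: str | Path, fit: FitResult) -> None:
    _dump_json(path, fit_result_to_dict(fit))


def load_fit(path: str | Path) -> FitResult:
    with open(path, encoding="utf-8") as fh:
        return fit_result_from_dict(json.load(fh))


def _dump_json(path: str | Path, payload) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
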