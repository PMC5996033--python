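"""End-to-end pipeline: simulate a cohort, fit both models, compare, report.

A :class:`PipelineConfig` (loadable from YAML or JSON) fully determines one
run: the training protocol, the generative agent model and parameters, the
cohort size, the fitting configuration and the output directory.  All
randomness flows from the single configured seed (agent ``i`` uses
``seed + i``), and every artifact embeds enough provenance to re-derive it,
so rerunning the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import analysis
from .comparison import compare_models
from .estimation import FitConfig, fit_set
from .exceptions import ConfigError
from .logio import (
    fit_result_to_dict,
    save_params,
    set_params_from_dict,
    write_log,
)
from .models import DayParams, DecisionWeights, SetParams
from .task import (
    ExperimentProtocol,
    TrialRecord,
    led_first_protocol,
    odor_first_protocol,
    simulate_agent,
    split_by_set,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; see :func:`load_pipeline_config`."""

    group: str
    n_days: tuple[int, ...]
    params: Mapping[str, SetParams]  # generating parameters per set
    out_dir: str
    trials_per_day: int = 100
    generative_model: str = "wam"
    models: tuple[str, ...] = ("wam", "nrl")
    n_agents: int = 1
    seed: int = 0
    decay: float = 1.0
    run_cv: bool = True
    fit: FitConfig = field(default_factory=FitConfig)

    def protocol(self) -> ExperimentProtocol:
        builder = odor_first_protocol if self.group == "odor_first" else led_first_protocol
        return builder(n_days=self.n_days, trials_per_day=self.trials_per_day)


def _expand_set_params(entry: Mapping, n_days: int) -> SetParams:
    """Accept either the full per-day JSON form or a one-day shorthand."""
    if "days" in entry:
        params = set_params_from_dict(entry)
        if params.n_days != n_days:
            raise ConfigError(
                f"params specify {params.n_days} days but the protocol has {n_days}"
            )
        return params
    weights = entry.get("weights")
    day = DayParams(
        alpha=float(entry["alpha"]),
        weights=None if weights is None else DecisionWeights(*map(float, weights)),
    )
    return SetParams(day_params=(day,) * n_days, beta=float(entry["beta"]))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        group = raw["group"]
        n_days = tuple(int(d) for d in raw["n_days"])
        out_dir = raw["out_dir"]
        raw_params = raw["params"]
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}")
    fit_cfg = FitConfig(**raw.get("fit", {}))
    builder = odor_first_protocol if group == "odor_first" else led_first_protocol
    labels = [s.set_label for s in builder(n_days=n_days).sets]
    params = {}
    for label, days in zip(labels, n_days):
        if label not in raw_params:
            raise ConfigError(f"{path}: no generating params for set {label}")
        params[label] = _expand_set_params(raw_params[label], days)
    return PipelineConfig(
        group=group,
        n_days=n_days,
        params=params,
        out_dir=out_dir,
        trials_per_day=int(raw.get("trials_per_day", 100)),
        generative_model=raw.get("generative_model", "wam"),
        models=tuple(raw.get("models", ("wam", "nrl"))),
        n_agents=int(raw.get("n_agents", 1)),
        seed=int(raw.get("seed", 0)),
        decay=float(raw.get("decay", 1.0)),
        run_cv=bool(raw.get("run_cv", True)),
        fit=fit_cfg,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> fit -> compare -> report; returns a manifest of artifacts.

    Writes, under ``config.out_dir``: per-agent behavioral logs and
    ground-truth parameter sidecars, per-set fit JSONs for each requested
    model, comparison JSONs (when both models are fit), and the report tables
    (success rates, stage splits, choice matrices, weight aggregates).
    """
    out = Path(config.out_dir)
    (out / "logs").mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    (out / "report").mkdir(exist_ok=True)
    protocol = config.protocol()
    manifest: dict = {"agents": [], "comparisons": [], "report": []}

    logs: dict[str, list[TrialRecord]] = {}
    for i in range(config.n_agents):
        agent = f"agent{i:02d}"
        records = simulate_agent(
            protocol,
            config.generative_model,
            config.params,
            seed=config.seed + i,
            decay=config.decay,
        )
        logs[agent] = records
        log_path = out / "logs" / f"{agent}.csv"
        write_log(log_path, config.group, records)
        save_params(out / "logs" / f"{agent}_truth.json", config.params)
        manifest["agents"].append(str(log_path))

    fits_by_animal: dict[str, dict[str, object]] = {}
    stages_by_animal: dict[str, dict[str, analysis.StageSplit]] = {}
    success_rows = []
    for agent, records in logs.items():
        fits_by_animal[agent] = {}
        stages_by_animal[agent] = {}
        for set_label, set_log in split_by_set(records).items():
            rates = analysis.daily_success_rate(set_log)
            split = analysis.stage_split(rates)
            stages_by_animal[agent][set_label] = split
            for day, (rate, stage) in enumerate(zip(rates, split.stages), start=1):
                success_rows.append((agent, set_label, day, rate, stage))
            if set(config.models) == {"wam", "nrl"}:
                cmp_result = compare_models(set_log, config.fit, run_cv=config.run_cv)
                fit_by_kind = {"wam": cmp_result.fit_wam, "nrl": cmp_result.fit_nrl}
                cmp_path = out / "fits" / f"{agent}_{set_label}_comparison.json"
                _write_comparison(cmp_path, agent, cmp_result)
                manifest["comparisons"].append(str(cmp_path))
            else:
                fit_by_kind = {
                    kind: fit_set(set_log, kind, config.fit) for kind in config.models
                }
            for kind, fit in fit_by_kind.items():
                fit_path = out / "fits" / f"{agent}_{set_label}_{kind}.json"
                with open(fit_path, "w", encoding="utf-8") as fh:
                    json.dump(fit_result_to_dict(fit), fh, indent=2, sort_keys=True)
                    fh.write("\n")
            if "wam" in fit_by_kind:
                fits_by_animal[agent][set_label] = fit_by_kind["wam"]

    report_dir = out / "report"
    success = pd.DataFrame(
        success_rows, columns=["animal", "set_label", "day", "success_rate", "stage"]
    )
    success.to_csv(report_dir / "success_rates.csv", index=False)
    manifest["report"].append(str(report_dir / "success_rates.csv"))

    if any(fits_by_animal.values()):
        agg = analysis.aggregate_weights(fits_by_animal, stages_by_animal)
        agg.by_day.to_csv(report_dir / "weights_by_day.csv", index=False)
        agg.by_stage.to_csv(report_dir / "weights_by_stage.csv", index=False)
        manifest["report"] += [
            str(report_dir / "weights_by_day.csv"),
            str(report_dir / "weights_by_stage.csv"),
        ]

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_comparison(path: Path, agent: str, cmp_result) -> None:
    payload = {
        "agent": agent,
        "set_label": cmp_result.set_label,
        "aic_score": cmp_result.aic.score,
        "d": cmp_result.aic.d,
        "n_days_included": cmp_result.aic.n_days_included,
        "included_days": list(cmp_result.aic.included_days),
        "cv_fractions": [list(p) for p in cmp_result.cv_fractions],
        "deterministic_fits": [list(p) for p in cmp_result.deterministic_fits],
        "success_rate": list(cmp_result.success_rate),
        "ll_wam": cmp_result.fit_wam.log_likelihood,
        "ll_nrl": cmp_result.fit_nrl.log_likelihood,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
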