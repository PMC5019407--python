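"""Run configuration, trajectory serialization and scenario execution.

Everything is plain text: trajectories are CSV with a JSON metadata sidecar
(parameters, seed, package version), configs are YAML.  Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import basic_model, extended_model, presets, schedule as sched_mod
from .extended_model import Perturbation

logger = logging.getLogger("fearcircuit")


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configurations."""


@dataclass
class RunConfig:
    """Declarative description of one simulation run.

    ``schedule`` is either a path to a schedule CSV or a builder spec: a list
    of ``{phase: ..., n_trials: ..., ...}`` mappings handed to the schedule
    builders in order.  ``params`` holds keyword overrides for the chosen
    model's parameter set; ``perturbations`` a list of perturbation mappings
    (extended model only).
    """

    model: str = "basic"
    params: dict = field(default_factory=dict)
    schedule: Any = None
    perturbations: list = field(default_factory=list)
    seed: int | None = None
    output: str | None = None

    def __post_init__(self) -> None:
        if self.model not in ("basic", "extended"):
            raise ConfigError(f"model must be 'basic' or 'extended', got {self.model!r}")
        if self.perturbations and self.model != "extended":
            raise ConfigError("perturbations require the extended model")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def build_schedule_from_spec(spec: Any, seed: int | None = None) -> sched_mod.TrialSchedule:
    """Materialize a schedule from a file path or a list of phase specs."""
    if isinstance(spec, (str, Path)):
        return sched_mod.TrialSchedule.from_csv(spec)
    if not isinstance(spec, list) or not spec:
        raise ConfigError("schedule spec must be a CSV path or a non-empty list of phases")
    parts = []
    for entry in spec:
        entry = dict(entry)
        phase = entry.pop("phase", None)
        n = entry.pop("n_trials", None)
        if phase == "conditioning":
            p_us = entry.pop("p_us", 1.0)
            us = entry.pop("us_intensity", 1.0)
            if p_us >= 1.0:
                parts.append(sched_mod.full_reinforcement(n, us))
            else:
                parts.append(
                    sched_mod.partial_reinforcement(
                        n, p_us, us, seed=entry.pop("seed", seed),
                        mode=entry.pop("mode", "bernoulli"),
                    )
                )
        elif phase in ("extinction", "resting", "retrieval"):
            parts.append(getattr(sched_mod, phase)(n))
        else:
            raise ConfigError(f"unknown phase spec {phase!r}")
        if entry:
            raise ConfigError(f"unused keys in phase spec: {sorted(entry)}")
    return sched_mod.concat(*parts)


def build_perturbations(specs: list) -> list[Perturbation]:
    perts = []
    for s in specs:
        s = dict(s)
        window = s.get("window")
        if isinstance(window, list):
            s["window"] = tuple(window)
        perts.append(
            Perturbation(
                mode=s["mode"], window=s["window"],
                drive=s.get("drive"), target=s.get("target", "E1"),
            )
        )
    return perts


def write_trajectory(
    records: list, path: str | Path, metadata: dict | None = None
) -> Path:
    """Write a trajectory CSV plus a ``<path>.meta.json`` sidecar."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if records and hasattr(records[0], "E2"):
        frame = extended_model.records_to_frame_ext(records)
    else:
        frame = basic_model.records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = {"package_version": __version__, **(metadata or {})}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1, default=str) + "\n")
    return path


@dataclass
class ScenarioResult:
    name: str
    schedule: sched_mod.TrialSchedule
    records: list
    params: Any
    perturbations: list
    output_path: Path | None = None


def run_scenario(
    preset_name: str,
    overrides: dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> ScenarioResult:
    """Run a named scenario preset end to end.

    ``overrides`` may replace model parameters (``params``) or the RNG seed
    of seeded presets.  When ``outdir`` is given, the trajectory CSV and its
    metadata sidecar are written there.
    """
    preset = presets.get_preset(preset_name)
    scenario = preset.build(seed=seed, **(overrides or {}))
    for label, a, b in scenario.schedule.segments:
        logger.info("phase %s: trials [%d, %d)", label, a, b)
    for pert in scenario.perturbations:
        logger.info("perturbation %s over %r", pert.mode, pert.window)
    if scenario.model == "basic":
        records = basic_model.run(scenario.schedule, scenario.params)
    else:
        records = extended_model.run_ext(
            scenario.schedule, scenario.params, perturbations=scenario.perturbations
        )
    out_path = None
    if outdir is not None:
        out_path = Path(outdir) / f"{preset_name}.csv"
        write_trajectory(
            records,
            out_path,
            metadata={
                "scenario": preset_name,
                "model": scenario.model,
                "params": dataclasses.asdict(scenario.params),
                "seed": scenario.seed,
                "perturbations": [dataclasses.asdict(p) for p in scenario.perturbations],
            },
        )
    return ScenarioResult(
        name=preset_name,
        schedule=scenario.schedule,
        records=records,
        params=scenario.params,
        perturbations=scenario.perturbations,
        output_path=out_path,
    )
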