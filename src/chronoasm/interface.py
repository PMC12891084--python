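"""Configuration, serialization and seed management for the command line.

Configs are YAML (JSON is valid YAML) with one section per concern::

    model:      keys mirroring the model parameter table (lambda0, rho, ...)
    drug:       preset name and/or explicit rates (per hour) and efficacy a
    schedule:   mode, phase_h, f, start_day, n_days, dosing_interval_h
    protocol:   burn_in_days, dosing_days, measure_days, n_phases, n_runs
    sim:        duration_h, dt, seed, record_stride
    experiment: a_grid, fractions, rho_grid, lambda0_grid, fixture_days, phases

All times in configs are hours (or days where named so); everything internal
runs in seconds — the conversion happens here, once.  Unknown keys are
rejected by name rather than silently ignored.  A run manifest (config
snapshot, root seed, package version) is written next to every output so any
published CSV can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from . import __version__
from .core_dynamics import ModelParams
from .experiments import DESK_PROTOCOL, FULL_PROTOCOL, ExperimentProtocol
from .pharmacology import DrugParams, SECONDS_PER_HOUR, get_drug

__all__ = [
    "ConfigError",
    "ConfigBundle",
    "load_config",
    "config_to_dict",
    "write_config",
    "RunManifest",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


_MODEL_KEYS = {
    "omega_discharge",
    "alpha",
    "beta",
    "n_nodes",
    "adjacency",
    "tau_fast",
    "lambda0",
    "rho",
    "gamma",
    "mu",
    "omega_s",
    "k_slow",
}
_DRUG_KEYS = {"preset", "name", "ka_per_h", "ke_per_h", "a"}
_SCHEDULE_KEYS = {"mode", "phase_h", "f", "start_day", "n_days", "dosing_interval_h"}
_PROTOCOL_KEYS = {"burn_in_days", "dosing_days", "measure_days", "n_phases", "n_runs"}
_SIM_KEYS = {"duration_h", "dt", "seed", "record_stride"}
_EXPERIMENT_KEYS = {
    "a_grid",
    "fractions",
    "rho_grid",
    "lambda0_grid",
    "fixture_days",
    "phases",
}
_SECTIONS = {
    "model": _MODEL_KEYS,
    "drug": _DRUG_KEYS,
    "schedule": _SCHEDULE_KEYS,
    "protocol": _PROTOCOL_KEYS,
    "sim": _SIM_KEYS,
    "experiment": _EXPERIMENT_KEYS,
}


@dataclass
class ConfigBundle:
    """Validated parameter bundle built from a config file."""

    params: ModelParams
    drug: Optional[DrugParams] = None
    schedule: Dict[str, Any] = field(default_factory=dict)
    protocol: Optional[ExperimentProtocol] = None
    sim: Dict[str, Any] = field(default_factory=dict)
    experiment: Dict[str, Any] = field(default_factory=dict)


def _check_keys(section: str, mapping: Dict[str, Any]) -> None:
    allowed = _SECTIONS[section]
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key '{section}.{key}'")


def _build_model(raw: Dict[str, Any]) -> ModelParams:
    _check_keys("model", raw)
    kwargs = dict(raw)
    if "adjacency" in kwargs:
        adjacency = np.asarray(kwargs["adjacency"], dtype=float)
        n = int(kwargs.get("n_nodes", ModelParams.n_nodes))
        if adjacency.shape != (n, n):
            raise ConfigError(
                f"'model.adjacency' must be an {n}x{n} matrix, got {adjacency.shape}"
            )
        kwargs["adjacency"] = adjacency
    try:
        return ModelParams(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid 'model' section: {exc}") from exc


def _build_drug(raw: Dict[str, Any]) -> DrugParams:
    _check_keys("drug", raw)
    if "preset" in raw:
        try:
            drug = get_drug(raw["preset"])
        except KeyError as exc:
            raise ConfigError(f"unknown value for 'drug.preset': {raw['preset']!r}") from exc
        if "a" in raw:
            drug = drug.with_a(float(raw["a"]))
        extra = set(raw) - {"preset", "a"}
        if extra:
            raise ConfigError(
                f"'drug.{sorted(extra)[0]}' cannot be combined with 'drug.preset'"
            )
        return drug
    required = {"name", "ka_per_h", "ke_per_h", "a"}
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"missing key 'drug.{sorted(missing)[0]}'")
    try:
        return DrugParams(
            name=str(raw["name"]),
            ka=float(raw["ka_per_h"]) / SECONDS_PER_HOUR,
            ke=float(raw["ke_per_h"]) / SECONDS_PER_HOUR,
            a=float(raw["a"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'drug' section: {exc}") from exc


def _build_protocol(raw: Dict[str, Any], scale: str) -> ExperimentProtocol:
    _check_keys("protocol", raw)
    base = FULL_PROTOCOL if scale == "full" else DESK_PROTOCOL
    try:
        return dataclasses.replace(base, **{k: int(v) for k, v in raw.items()})
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid 'protocol' section: {exc}") from exc


def load_config(path=None, scale: str = "desk") -> ConfigBundle:
    """Load and validate a config file, filling defaults for absent keys.

    ``path=None`` yields the full default bundle.  ``scale`` selects the
    protocol defaults: "full" is the complete experimental protocol, "desk"
    a reduced one that runs in minutes.
    """
    raw: Dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping of sections")
    if scale not in ("full", "desk"):
        raise ConfigError(f"unknown value for 'scale': {scale!r}")
    for section in raw:
        if section not in _SECTIONS:
            raise ConfigError(f"unknown section '{section}'")
        if raw[section] is None:
            raw[section] = {}
        elif not isinstance(raw[section], dict):
            raise ConfigError(f"section '{section}' must be a mapping")

    params = _build_model(raw.get("model", {}))
    drug = _build_drug(raw["drug"]) if "drug" in raw else None

    schedule = dict(raw.get("schedule", {}))
    _check_keys("schedule", schedule)

    protocol = _build_protocol(raw.get("protocol", {}), scale)

    sim = dict(raw.get("sim", {}))
    _check_keys("sim", sim)
    sim.setdefault("duration_h", 24.0)
    sim.setdefault("dt", 0.001)
    sim.setdefault("seed", 0)
    sim.setdefault("record_stride", 10)
    if float(sim["dt"]) <= 0:
        raise ConfigError("'sim.dt' must be positive")

    experiment = dict(raw.get("experiment", {}))
    _check_keys("experiment", experiment)

    return ConfigBundle(
        params=params,
        drug=drug,
        schedule=schedule,
        protocol=protocol,
        sim=sim,
        experiment=experiment,
    )


def config_to_dict(bundle: ConfigBundle) -> Dict[str, Any]:
    """Round-trippable plain-dict form of a bundle."""
    model = dataclasses.asdict(bundle.params)
    model["adjacency"] = bundle.params.adjacency.tolist()
    out: Dict[str, Any] = {"model": model, "sim": dict(bundle.sim)}
    if bundle.drug is not None:
        out["drug"] = {
            "name": bundle.drug.name,
            "ka_per_h": bundle.drug.ka * SECONDS_PER_HOUR,
            "ke_per_h": bundle.drug.ke * SECONDS_PER_HOUR,
            "a": bundle.drug.a,
        }
    if bundle.schedule:
        out["schedule"] = dict(bundle.schedule)
    if bundle.protocol is not None:
        out["protocol"] = {
            k: getattr(bundle.protocol, k) for k in sorted(_PROTOCOL_KEYS)
        }
    if bundle.experiment:
        out["experiment"] = dict(bundle.experiment)
    return out


def write_config(bundle: ConfigBundle, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(bundle), sort_keys=True))


@dataclass
class RunManifest:
    """Everything needed to regenerate a command's outputs bit for bit."""

    command: str
    root_seed: int
    config: Dict[str, Any]
    child_seeds: Dict[str, int] = field(default_factory=dict)
    version: str = __version__
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
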