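"""Configuration loading/validation, presets, and tabular writers.

Experiments are described by a small structured config (JSON or TOML):
model kind, kinetic-parameter overrides, circadian settings, dose
schedule, DUO preset or explicit coupling parameters, and solver
settings.  Unknown keys are rejected so typos fail loudly.  Tables are
written as CSV (full double precision, NaN spelled out) or JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from .duo import DUOParams, PRESETS
from .dynamics import SolverSettings
from .forcing import CircadianConfig, DoseSchedule
from .model import AutoreceptorCalibration, ReducedParams

__all__ = [
    "ExperimentSpec",
    "RunManifest",
    "ConfigError",
    "load_config",
    "spec_from_dict",
    "write_table",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentSpec:
    """Validated description of one reproducible run."""

    name: str = "nominal"
    model: str = "reduced"  # "reduced" | "duo"
    params: ReducedParams = field(default_factory=ReducedParams)
    calib: AutoreceptorCalibration = field(default_factory=AutoreceptorCalibration)
    circadian: CircadianConfig = field(default_factory=CircadianConfig)
    schedule: Optional[DoseSchedule] = None
    duo: Optional[DUOParams] = None
    solver: SolverSettings = field(default_factory=SolverSettings)
    days: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("reduced", "duo"):
            raise ConfigError(f"model must be 'reduced' or 'duo', got {self.model!r}")
        if self.model == "duo" and self.duo is None:
            raise ConfigError("model 'duo' requires a duo preset or parameter block")


def _build(cls, block: dict, label: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in {label}: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {label}: {exc}") from exc


_TOP_KEYS = {"name", "model", "params", "calib", "circadian", "schedule",
             "duo", "duo_preset", "solver", "days", "seed"}


def spec_from_dict(raw: dict) -> ExperimentSpec:
    """Validate a raw mapping into an :class:`ExperimentSpec`.

    An empty mapping yields the full nominal default run (published
    baseline parameters, circadian forcing on, no doses).
    """
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key in ("name", "model", "days", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "params" in raw:
        base = {f.name: getattr(ReducedParams(), f.name)
                for f in dataclasses.fields(ReducedParams)}
        unknown = set(raw["params"]) - set(base)
        if unknown:
            raise ConfigError(f"unknown key(s) in params: {sorted(unknown)}")
        base.update(raw["params"])
        kwargs["params"] = _build(ReducedParams, base, "params")
    if "calib" in raw:
        kwargs["calib"] = _build(AutoreceptorCalibration, raw["calib"], "calib")
    if "circadian" in raw:
        kwargs["circadian"] = _build(CircadianConfig, raw["circadian"], "circadian")
    if "schedule" in raw and raw["schedule"] is not None:
        block = dict(raw["schedule"])
        if "times" in block:
            block["times"] = tuple(block["times"])
        kwargs["schedule"] = _build(DoseSchedule, block, "schedule")
    if "solver" in raw:
        kwargs["solver"] = _build(SolverSettings, raw["solver"], "solver")
    if "duo_preset" in raw and "duo" in raw:
        raise ConfigError("give either 'duo_preset' or 'duo', not both")
    if "duo_preset" in raw:
        preset = raw["duo_preset"]
        if preset not in PRESETS:
            raise ConfigError(f"unknown duo_preset {preset!r}; available: {sorted(PRESETS)}")
        duo = PRESETS[preset]
        if "params" in kwargs:
            duo = dataclasses.replace(duo, reduced=kwargs["params"])
        kwargs["duo"] = duo
    elif "duo" in raw and raw["duo"] is not None:
        block = dict(raw["duo"])
        if "params" in kwargs:
            block.setdefault("reduced", kwargs["params"])
        kwargs["duo"] = _build(DUOParams, block, "duo")
    return ExperimentSpec(**kwargs)


def load_config(path: "str | Path") -> ExperimentSpec:
    """Load and validate a JSON or TOML experiment config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib

        raw = tomllib.loads(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return spec_from_dict(raw)


@dataclass(frozen=True)
class RunManifest:
    """Machine-readable provenance record written beside every output."""

    name: str
    spec_hash: str
    provenance: str  # preset name or config path
    version: str
    timestamp: str
    seed: int

    @classmethod
    def for_spec(cls, spec: ExperimentSpec, provenance: str = "builtin") -> "RunManifest":
        from . import __version__

        blob = json.dumps(_spec_to_jsonable(spec), sort_keys=True).encode()
        return cls(
            name=spec.name,
            spec_hash=hashlib.sha256(blob).hexdigest()[:16],
            provenance=provenance,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            seed=spec.seed,
        )

    def write(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _spec_to_jsonable(spec: ExperimentSpec) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {f.name: conv(getattr(spec, f.name)) for f in dataclasses.fields(spec)}


def write_table(table: pd.DataFrame, path: "str | Path", format: Optional[str] = None) -> None:
    """Write a table as CSV or JSON with lossless numeric round-trip.

    Floats are written with 17 significant digits (round-trip exact for
    IEEE doubles); NaN cells are serialized explicitly as ``NaN``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        table.to_csv(path, index=False, float_format="%.17g", na_rep="NaN")
    elif fmt == "json":
        path.write_text(table.to_json(orient="table", index=False, double_precision=15) + "\n")
    else:
        raise ConfigError(f"unsupported table format: {fmt!r}")
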