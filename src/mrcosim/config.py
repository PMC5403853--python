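"""Configuration schema, validation and run manifests.

A run is described by a single YAML file with four sections — ``engine``,
``models``, ``coupling`` and ``sweep`` — all optional, all defaulted.  Unknown
keys are rejected and every validation error names the offending key.  The
fully defaulted configuration is snapshotted into a JSON run manifest that is
sufficient to rerun the simulation exactly (the whole stack is deterministic).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .engine import EngineConfig
from .models import (
    TC_FAST,
    TC_SLOW,
    BiochemicalParams,
    CoupledTestCase,
    ElectricalParams,
    PulseProtocol,
    SyntheticTwoRateProblem,
)

__all__ = [
    "ConfigError",
    "RunSettings",
    "RunManifest",
    "load_config",
    "write_config",
    "build_problem",
    "testcase_config_path",
]


def testcase_config_path(variant: str) -> Path:
    """Path of the canonical shipped parameter file for a test-case variant."""
    from importlib import resources

    name = {TC_SLOW: "tc_slow.yaml", TC_FAST: "tc_fast.yaml"}.get(variant)
    if name is None:
        raise ConfigError(f"no shipped config for variant {variant!r}")
    return Path(str(resources.files("mrcosim").joinpath("data", name)))

FLOAT_FMT = "%.17g"  # 17 significant digits keeps regression output bit-stable


class ConfigError(ValueError):
    """Configuration validation failure; the message names the key."""


@dataclass
class SweepSettings:
    tolerances: list = field(default_factory=lambda: [1e-5, 1e-6, 1e-7])
    observables: list = field(default_factory=list)
    t_eval: float | None = None


@dataclass
class ModelSettings:
    problem: str = "synthetic"  # or "testcase"
    variant: str = TC_SLOW
    signal_speed: str = "slow"
    stiffness_ratio: float = 1000.0
    coupling_strength: float = 0.5
    rel_tol: float = 1e-6
    electrical: dict = field(default_factory=dict)
    biochemical: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)


@dataclass
class RunSettings:
    engine: EngineConfig = field(default_factory=EngineConfig)
    models: ModelSettings = field(default_factory=ModelSettings)
    coupling: dict = field(default_factory=dict)
    sweep: SweepSettings = field(default_factory=SweepSettings)

    def to_dict(self) -> dict:
        return {
            "engine": asdict(self.engine),
            "models": asdict(self.models),
            "coupling": dict(self.coupling),
            "sweep": asdict(self.sweep),
        }


def _check_keys(section: str, given: dict, allowed) -> None:
    for key in given:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {section}.{key!r}; allowed keys: {sorted(allowed)}"
            )


def _dataclass_from(section: str, cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, data, fields)
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} section: {exc}") from exc


def _validate(settings: RunSettings) -> RunSettings:
    m = settings.models
    if m.problem not in ("synthetic", "testcase"):
        raise ConfigError(
            f"models.problem must be 'synthetic' or 'testcase', got {m.problem!r}"
        )
    if m.variant not in (TC_FAST, TC_SLOW):
        raise ConfigError(
            f"models.variant must be {TC_FAST!r} or {TC_SLOW!r}, got {m.variant!r}"
        )
    if m.signal_speed not in ("fast", "slow"):
        raise ConfigError(
            f"models.signal_speed must be 'fast' or 'slow', got {m.signal_speed!r}"
        )
    if not m.rel_tol > 0:
        raise ConfigError(f"models.rel_tol must be positive, got {m.rel_tol}")
    for tol in settings.sweep.tolerances:
        if not tol > 0:
            raise ConfigError(f"sweep.tolerances entries must be positive, got {tol}")
    return settings


def load_config(path) -> RunSettings:
    """Load and validate a YAML run configuration; all defaults materialized."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    _check_keys("<root>", data, {"engine", "models", "coupling", "sweep"})

    try:
        engine = _dataclass_from("engine", EngineConfig, data.get("engine", {}) or {})
    except ConfigError:
        raise
    except ValueError as exc:  # EngineConfig __post_init__ enum checks
        raise ConfigError(f"invalid engine section: {exc}") from exc
    models = _dataclass_from("models", ModelSettings, data.get("models", {}) or {})
    sweep = _dataclass_from("sweep", SweepSettings, data.get("sweep", {}) or {})
    coupling = data.get("coupling", {}) or {}
    if not isinstance(coupling, dict):
        raise ConfigError("coupling section must be a mapping")

    # nested model-parameter overrides are validated against the dataclasses
    _check_keys(
        "models.electrical",
        models.electrical,
        {f.name for f in dataclasses.fields(ElectricalParams)},
    )
    _check_keys(
        "models.biochemical",
        models.biochemical,
        {f.name for f in dataclasses.fields(BiochemicalParams)},
    )
    _check_keys(
        "models.protocol",
        models.protocol,
        {f.name for f in dataclasses.fields(PulseProtocol)},
    )
    return _validate(RunSettings(engine=engine, models=models, coupling=coupling, sweep=sweep))


def write_config(settings: RunSettings, path) -> Path:
    """Serialize settings to YAML so that load_config round-trips exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(settings.to_dict(), fh, sort_keys=False)
    return path


def build_problem(settings: RunSettings):
    """Instantiate the configured problem (synthetic benchmark or test case)."""
    m = settings.models
    if m.problem == "synthetic":
        kwargs = dict(m.synthetic)
        return SyntheticTwoRateProblem(
            stiffness_ratio=m.stiffness_ratio,
            coupling_strength=m.coupling_strength,
            signal_speed=m.signal_speed,
            **kwargs,
        )
    elec = ElectricalParams(**m.electrical)
    bioch = BiochemicalParams(**m.biochemical)
    protocol = PulseProtocol(**m.protocol)
    if settings.coupling.get("c1") is not None:
        bioch.c1 = float(settings.coupling["c1"])
    return CoupledTestCase(
        variant=m.variant,
        elec_params=elec,
        bioch_params=bioch,
        protocol=protocol,
    )


@dataclass
class RunManifest:
    """Snapshot of one run: config, version, counters, outputs, status."""

    config: dict
    code_version: str
    status: str = "pending"
    message: str = ""
    counters: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def validate_outputs(self) -> bool:
        return all(Path(p).exists() for p in self.outputs)
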