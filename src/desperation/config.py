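"""Run configuration: model parameters plus run settings, file round-trip.

A config file (JSON or YAML) holds an optional ``model`` section with
:class:`~desperation.core.ModelParams` fields (absent keys take the
canonical defaults) and an optional ``run`` section with execution
settings.  Unknown keys anywhere are rejected with an error naming the
key.  A flat mapping is also accepted and treated as a model section.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import ModelParams, ParameterError, _read_mapping

__all__ = ["RunConfig", "RunSettings", "load_config", "save_config"]

MODES = ("solve", "simulate", "sweep", "shock", "critical-fraction")


@dataclass
class RunSettings:
    mode: str = "simulate"
    steps: int | None = None
    reps: int = 5
    seed: int = 0
    out: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"run.mode must be one of {MODES}, got {self.mode!r}")
        if self.steps is not None and self.steps < 1:
            raise ParameterError("run.steps must be >= 1")
        if self.reps < 1:
            raise ParameterError("run.reps must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunSettings":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown run key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)


@dataclass
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(), "run": dataclasses.asdict(self.run)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration file."""
    data = _read_mapping(Path(path))
    if set(data) <= {"model", "run"}:
        model = ModelParams.from_dict(data.get("model") or {})
        run = RunSettings.from_dict(data.get("run") or {})
    else:
        # flat mapping of model parameters
        model = ModelParams.from_dict(data)
        run = RunSettings()
    return RunConfig(model=model, run=run)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
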