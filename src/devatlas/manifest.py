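"""Run manifests: declarative stage execution with provenance capture.

A manifest names a pipeline stage, its input paths, a parameter map and a
seed.  Running it executes the stage, writes the outputs, and serializes the
manifest (plus a line-delimited JSON log) next to them, so every artifact
records how it was produced and deterministic stages reproduce bit-exactly
from their manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

__all__ = ["RunManifest", "ConfigError", "run_stage", "register_stage", "STAGES"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Manifest does not validate against the stage schema."""


@dataclass
class RunManifest:
    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    schema_version: int = SCHEMA_VERSION
    tool_version: str = ""
    started: str = ""
    finished: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("manifest must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown manifest key: {key!r}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


# stage registry: name -> (callable(manifest) -> dict of outputs, schema)
STAGES: dict[str, tuple[Callable[[RunManifest], dict], dict]] = {}


def register_stage(name: str, allowed_params: set[str],
                   required_inputs: set[str] = frozenset()):
    def deco(fn):
        STAGES[name] = (fn, {"params": allowed_params,
                             "inputs": required_inputs})
        return fn
    return deco


def _validate(manifest: RunManifest) -> None:
    if manifest.stage not in STAGES:
        raise ConfigError(
            f"unknown stage {manifest.stage!r}; known: {sorted(STAGES)}")
    _, schema = STAGES[manifest.stage]
    for key in manifest.params:
        if key not in schema["params"]:
            raise ConfigError(
                f"stage {manifest.stage!r}: unknown parameter {key!r} "
                f"(allowed: {sorted(schema['params'])})")
    for key in schema["inputs"]:
        if key not in manifest.inputs:
            raise ConfigError(
                f"stage {manifest.stage!r}: missing input {key!r}")


def run_stage(manifest: RunManifest) -> dict:
    """Validate, execute, and write manifest + JSONL log beside the outputs."""
    from . import __version__

    _validate(manifest)
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.tool_version = __version__
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")

    log_path = out_dir / f"{manifest.stage}.log.jsonl"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(_JsonFormatter())
    root = logging.getLogger("devatlas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        fn, _ = STAGES[manifest.stage]
        outputs = fn(manifest)
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_yaml(out_dir / f"{manifest.stage}.manifest.yaml")
    return outputs


class _JsonFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        return json.dumps({
            "t": self.formatTime(record, "%Y-%m-%dT%H:%M:%S"),
            "level": record.levelname,
            "name": record.name,
            "msg": record.getMessage(),
        })
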