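"""Run configuration, schema validation, and deterministic seeding.

A run is described by a YAML document with optional blocks mirroring the
module-level config dataclasses (``plume``, ``encounter_train``,
``detection``, ``smoothing``, ``events``, ``turn_model``, ``agent``,
``arena``) plus a global ``seed``.  Every source of randomness in a run is
derived from the global seed through :func:`derive_seed`, which hashes a
stable per-purpose label into an independent stream, so re-running any
stage with the same config reproduces identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .agent_sim import ArenaConfig
from .kinematics_events import EventDetectionConfig, SmoothingConfig
from .signal_encounters import EncounterDetectionConfig
from .synthetic_world import EncounterTrainConfig, PlumeConfig
from .turn_model import TurnModelParams

_BLOCKS = {
    "plume": PlumeConfig,
    "encounter_train": EncounterTrainConfig,
    "detection": EncounterDetectionConfig,
    "smoothing": SmoothingConfig,
    "events": EventDetectionConfig,
    "turn_model": TurnModelParams,
    "arena": ArenaConfig,
}


def derive_seed(global_seed: int, label: str) -> int:
    """Stable sub-seed (< 2**31) for a named purpose."""
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2 ** 31))


def derive_rng(global_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, label))


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    verbosity: int = 1
    blocks: dict = field(default_factory=dict)

    def get(self, name: str):
        if name not in _BLOCKS:
            raise ConfigError(f"unknown config block {name!r}")
        return self.blocks.get(name) or _BLOCKS[name]()


def _build_block(name: str, payload: dict):
    cls = _BLOCKS[name]
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(f"{name}: unknown fields {sorted(unknown)}")
    # YAML lists -> tuples for tuple-typed fields
    coerced = {k: tuple(v) if isinstance(v, list) else v
               for k, v in payload.items()}
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{name}: {e}") from e


def load_run_config(doc: dict) -> RunConfig:
    """Validate a parsed YAML document into a RunConfig."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    known = set(_BLOCKS) | {"seed", "verbosity"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    blocks = {}
    for name in _BLOCKS:
        if name in doc:
            payload = dict(doc[name] or {})
            if name == "plume" and "seed" not in payload:
                payload["seed"] = derive_seed(doc.get("seed", 0), "plume")
            if name == "encounter_train" and "seed" not in payload:
                payload["seed"] = derive_seed(doc.get("seed", 0), "encounter_train")
            blocks[name] = _build_block(name, payload)
    return RunConfig(seed=int(doc.get("seed", 0)),
                     verbosity=int(doc.get("verbosity", 1)), blocks=blocks)


def config_hash(doc: dict) -> str:
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]
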