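"""Run configuration: schema-checked YAML with injected defaults.

The ``external_tools`` block records the documented parameters of the
upstream aligner/caller stack (chimeric-score drop cutoff, minimum
expected supporting reads) purely as provenance metadata; the internal
computation never consumes them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping, Optional

import yaml

from .models import DetectorConfig, ValidationError


class ConfigError(ValidationError):
    """Configuration file violates the schema."""


_EXTERNAL_DEFAULTS = {"chim_score_drop_max": 30, "arriba_min_expected": 0.8}

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "detector": {"boundary_tolerance": int, "min_split_reads": int,
                 "min_spanning_pairs": int, "min_total_support": int},
    "harmonizer": {"bp_tolerance": int, "policy": str},
    "external_tools": {"chim_score_drop_max": (int, float),
                       "arriba_min_expected": (int, float)},
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 42
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    bp_tolerance: int = 10
    policy: str = "union"
    external_tools: Mapping[str, float] = field(
        default_factory=lambda: dict(_EXTERNAL_DEFAULTS))

    def as_dict(self) -> dict:
        return {"seed": self.seed,
                "detector": asdict(self.detector),
                "harmonizer": {"bp_tolerance": self.bp_tolerance,
                               "policy": self.policy},
                "external_tools": dict(self.external_tools)}

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _check_keys(data: Mapping, schema: Mapping, path: str = "") -> None:
    for key, value in data.items():
        here = f"{path}{key}"
        if key not in schema:
            raise ConfigError(f"unknown configuration key: {here}")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here}: expected a mapping")
            _check_keys(value, expected, here + ".")
        else:
            if isinstance(value, bool) or not isinstance(value, expected):
                raise ConfigError(f"{here}: expected {expected}, got {value!r}")


def validate_config(source: Optional[str] = None,
                    data: Optional[Mapping] = None) -> RunConfig:
    """Load a YAML config file (or pre-parsed mapping) into a RunConfig.

    Unknown keys are rejected with their key path; absent keys take
    defaults; an empty file yields the all-defaults configuration.
    """
    if data is None:
        if source is None:
            data = {}
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(data, _SCHEMA)
    det = dict(data.get("detector", {}))
    harm = dict(data.get("harmonizer", {}))
    ext = {**_EXTERNAL_DEFAULTS, **dict(data.get("external_tools", {}))}
    if "external_tools" in data:
        warnings.warn("external_tools parameters are provenance metadata only; "
                      "they are not consumed by internal computation",
                      stacklevel=2)
    try:
        detector = DetectorConfig(**det)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"detector: {exc}") from exc
    bp_tol = int(harm.get("bp_tolerance", 10))
    if bp_tol < 0:
        raise ConfigError("harmonizer.bp_tolerance: must be >= 0")
    policy = str(harm.get("policy", "union"))
    if policy not in ("union", "majority", "intersection"):
        raise ConfigError(f"harmonizer.policy: unknown policy {policy!r}")
    return RunConfig(seed=int(data.get("seed", 42)), detector=detector,
                     bp_tolerance=bp_tol, policy=policy, external_tools=ext)


def provenance_lines(config: RunConfig, version: str) -> list[str]:
    return [f"junctionscope {version}",
            f"seed={config.seed}",
            f"config_hash={config.config_hash}"]
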