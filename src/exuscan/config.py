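"""Run configuration: defaults, YAML config files, and flag overrides.

Config files are flat ``key: value`` YAML documents using the same names
as the reference operating point (th1, th2, th3, r0, r1, ...), so runs
are auditable at a glance.  Precedence: flags > config file > defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .detector import DetectionConfig
from .errors import ConfigError
from .evaluation import EvalConfig
from .optic_disc import OdConfig

_DETECTION_KEYS = {f.name for f in fields(DetectionConfig)}
_OD_KEYS = {f.name for f in fields(OdConfig)}
_EVAL_KEYS = {f.name for f in fields(EvalConfig)}
_TOP_KEYS = {"channel"}


@dataclass
class RunConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    od: OdConfig = field(default_factory=OdConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    channel: str = "green"

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"channel": self.channel}
        for sub in (self.detection, self.od, self.eval):
            for f in fields(sub):
                out[f.name] = getattr(sub, f.name)
        return out


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML config file, validating key names."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key: value mapping")
    known = _DETECTION_KEYS | _OD_KEYS | _EVAL_KEYS | _TOP_KEYS
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys in {path}: {', '.join(sorted(unknown))}")
    return raw


def resolve_config(
    file_values: dict[str, Any] | None = None, flag_values: dict[str, Any] | None = None
) -> RunConfig:
    """Merge defaults, config-file values, and CLI flags (flags win)."""
    merged: dict[str, Any] = {}
    for source in (file_values or {}), {k: v for k, v in (flag_values or {}).items() if v is not None}:
        merged.update(source)
    det = {k: v for k, v in merged.items() if k in _DETECTION_KEYS}
    od = {k: v for k, v in merged.items() if k in _OD_KEYS}
    ev = {k: v for k, v in merged.items() if k in _EVAL_KEYS}
    return RunConfig(
        detection=DetectionConfig(**det),
        od=OdConfig(**od),
        eval=EvalConfig(**ev),
        channel=merged.get("channel", "green"),
    )
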