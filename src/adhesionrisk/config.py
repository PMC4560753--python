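"""Optional YAML configuration for the scoring tool.

With no config file the published score is reproduced exactly.  A config
may override the risk-threshold intervals (for sensitivity exploration —
they must still partition each achievable range), default strictness, and
the logging level::

    thresholds:
      preoperative:  {low: [0, 12], medium: [13, 24], high: [25, 36]}
      perioperative: {low: [3, 17], medium: [18, 28], high: [29, 31]}
    strict: false
    log_level: INFO
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scoring import DEFAULT_THRESHOLDS, ThresholdTable


@dataclass(frozen=True)
class Config:
    thresholds: ThresholdTable = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    strict: bool = False
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; ``None`` returns the published defaults."""
    if path is None:
        return Config()
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    unknown = set(payload) - {"thresholds", "strict", "log_level"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    thresholds = DEFAULT_THRESHOLDS
    if "thresholds" in payload:
        spec = payload["thresholds"]
        kwargs = {}
        for kind in ("preoperative", "perioperative"):
            if kind in spec:
                kwargs[kind] = {cat: tuple(iv) for cat, iv in spec[kind].items()}
        thresholds = ThresholdTable(**kwargs)
    cfg = Config(
        thresholds=thresholds,
        strict=bool(payload.get("strict", False)),
        log_level=str(payload.get("log_level", "INFO")).upper(),
    )
    logging.getLogger("adhesionrisk").setLevel(cfg.log_level)
    return cfg
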