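"""Structured YAML configuration shared by every CLI subcommand.

Sections: ``data``, ``selection``, ``model``, ``monitor``, ``policy``.
Missing sections/keys fall back to the package defaults; unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .bilstm import BiLSTMConfig
from .mi import DEFAULT_K, DEFAULT_LAMBDA
from .pipeline import PolicyConfig

__all__ = ["AppConfig", "load_config"]


@dataclass
class DataSection:
    target: str = "BOD_out"
    lag_shifts: dict[str, int] = field(default_factory=dict)  # optional per-variable realignment


@dataclass
class SelectionSection:
    k: int = DEFAULT_K
    threshold_lambda: float = DEFAULT_LAMBDA
    jitter_seed: int = 0


@dataclass
class AppConfig:
    data: DataSection = field(default_factory=DataSection)
    selection: SelectionSection = field(default_factory=SelectionSection)
    model: BiLSTMConfig = field(default_factory=BiLSTMConfig)
    policy: PolicyConfig = field(default_factory=PolicyConfig)


_SECTIONS = {
    "data": DataSection,
    "selection": SelectionSection,
    "model": BiLSTMConfig,
    "policy": PolicyConfig,
    # "monitor" keys live on PolicyConfig (delta, absolute_mode); accepted
    # as an alias section for readability of config files
    "monitor": PolicyConfig,
}


def load_config(path: str | None) -> AppConfig:
    """Load a YAML config; `None` gives all defaults."""
    cfg = AppConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        if payload is None:
            continue
        target = cfg.policy if section == "monitor" else getattr(cfg, section)
        valid = {f.name for f in fields(target)}
        for key, value in payload.items():
            if key not in valid:
                raise ValueError(f"unknown key {key!r} in section {section!r}")
            setattr(target, key, value)
    return cfg
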