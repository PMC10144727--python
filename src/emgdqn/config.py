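"""YAML run configuration: sections window / agent / reward / synthetic /
network, with every field defaulting to the tuned operating point."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .agent import AgentConfig
from .env import RewardSpec
from .network import NetworkArch
from .preprocess import WindowSpec
from .synthetic import ConfigurationError, SynthConfig


@dataclass
class RunConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    agent: AgentConfig = field(default_factory=AgentConfig)
    reward: RewardSpec = field(default_factory=RewardSpec)
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    network: NetworkArch = field(default_factory=NetworkArch)


_SECTIONS = {
    "window": WindowSpec,
    "agent": AgentConfig,
    "reward": RewardSpec,
    "synthetic": SynthConfig,
    "network": NetworkArch,
}


def _build(cls, data: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    if cls is NetworkArch and "hidden" in data:
        data = {**data, "hidden": tuple(data["hidden"])}
    return cls(**data)


def load_run_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file (None -> all defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration file must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)


def dump_run_config(config: RunConfig) -> str:
    """Render a RunConfig back to YAML (hidden sizes as a list)."""
    data = {name: asdict(getattr(config, name)) for name in _SECTIONS}
    data["network"]["hidden"] = list(data["network"]["hidden"])
    return yaml.safe_dump(data, sort_keys=True)
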