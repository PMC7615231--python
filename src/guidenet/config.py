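"""YAML <-> dataclass configuration plumbing for the CLI."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .model import PolicyPair
from .simulate import ScanSimConfig
from .train import TrainConfig

__all__ = ["load_train_config", "load_sim_config", "dump_config"]


def load_train_config(path: str | Path) -> TrainConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "policy_pair" in raw:
        probe, gaze = raw.pop("policy_pair").split("+")
        raw["policy_pair"] = PolicyPair(probe=probe, gaze=gaze)
    return TrainConfig(**raw)


def load_sim_config(path: str | Path) -> ScanSimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ScanSimConfig(**raw)


def dump_config(cfg, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    if "policy_pair" in d:
        d["policy_pair"] = f"{cfg.policy_pair.probe}+{cfg.policy_pair.gaze}"
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
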