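"""Run configuration shared by the CLI subcommands.

A YAML config file may pre-set any option; explicit command-line flags win.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .consistency import Thresholds

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    engine: str = "stub"
    hairpin_threshold: float = 0.20
    stem_threshold: float = 0.10
    bootstrap_n: int = 100
    bootstrap_runs: int = 1
    seed: int = 0
    gap_open: float = 7.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap N must be >= 1")
        if self.bootstrap_runs < 1:
            raise ValueError("bootstrap runs must be >= 1")
        # validates the ranges
        self.thresholds()

    def thresholds(self) -> Thresholds:
        return Thresholds(self.hairpin_threshold, self.stem_threshold)


def load_config(path: str | Path | None, overrides: dict) -> RunConfig:
    """Merge a YAML config (if any) under explicit CLI overrides."""
    base: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        names = {f.name for f in fields(RunConfig)}
        unknown = set(loaded) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base.update(loaded)
    base.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**base)
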