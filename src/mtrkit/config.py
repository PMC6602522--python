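"""Run configuration shared by the CLI subcommands.

Precedence: command-line flags > config file > defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class RunConfig:
    window_size: int = 31
    window_size_set: tuple[int, ...] = (21, 31, 41)
    fdr_threshold: float = 0.1
    fdr_scope: str = "joint"  # or "per_transcript"
    min_population_exomes: int = 15_000
    stratified_window_sizes: tuple[int, ...] = (31, 41)
    require_pass: bool = True
    missing_filter_passes: bool = False
    assembly: str = "GRCh37"  # documentation label echoed to outputs
    seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.window_size, *self.window_size_set, *self.stratified_window_sizes):
            if w < 3 or w % 2 == 0:
                raise ConfigError(f"window sizes must be odd and >= 3, got {w}")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ConfigError(f"fdr_threshold {self.fdr_threshold} outside (0, 1)")
        if self.fdr_scope not in ("joint", "per_transcript"):
            raise ConfigError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.min_population_exomes < 0:
            raise ConfigError("min_population_exomes must be >= 0")


def load_config(
    path: Optional[str | Path] = None,
    overrides: Optional[dict] = None,
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus explicit overrides.

    Overrides with value None are ignored (flag not given).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            data[k] = v
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("window_size_set", "stratified_window_sizes"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)
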