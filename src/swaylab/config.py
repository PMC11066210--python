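"""YAML configuration loading.

A config file may carry two top-level tables:

``simulation:`` — overrides for :class:`swaylab.sway_synthesis.SimConfig`
fields (n_subjects, duration_s, fs, condition_av_targets, site_gains, ...).

``pipeline:`` — overrides for the analysis stages: ``selection_threshold``
(default 0.7), ``prune_threshold`` (default null = pruning off), ``trim_s``
(default 0.5), ``val_fraction`` (default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .sway_synthesis import SimConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    selection_threshold: float = 0.7
    prune_threshold: float | None = None
    trim_s: float = 0.5
    val_fraction: float = 0.2


def load_config(path: str | Path | None) -> tuple[SimConfig, PipelineConfig]:
    """Load simulation and pipeline settings; absent file → all defaults."""
    if path is None:
        return SimConfig(), PipelineConfig()
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(payload, dict):
        raise InvalidParameterError("config root must be a mapping")
    sim_kw = payload.get("simulation", {}) or {}
    pipe_kw = payload.get("pipeline", {}) or {}
    sim_fields = {f.name for f in fields(SimConfig)}
    pipe_fields = {f.name for f in fields(PipelineConfig)}
    unknown = (set(sim_kw) - sim_fields) | (set(pipe_kw) - pipe_fields)
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    sim = SimConfig(**sim_kw)
    sim.validate()
    return sim, PipelineConfig(**pipe_kw)
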