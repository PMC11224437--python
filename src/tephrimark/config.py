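"""Run configuration: TOML loading with strict key validation.

All randomness in a run flows from one global seed; per-stage seeds are
derived deterministically so stages can be rerun in isolation.
"""
from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

from .diagnostics import ScreenParams
from .simulate import SimConfig


@dataclass
class CaptureParams:
    min_identity: float = 0.85
    min_coverage: float = 0.8
    k: int = 15
    flank: int = 400
    join_dist: int = 100


@dataclass
class MatrixParams:
    trim_max_gap_frac: float = 0.5
    taus: list[float] = field(default_factory=lambda: [0.5, 0.75, 0.9, 1.0])


@dataclass
class TreeParams:
    bootstrap_reps: int = 100


@dataclass
class PiParams:
    n_times: int = 100


@dataclass
class DiagnosticsParams:
    target: str | None = None  # default: first taxon
    window: int = 200
    step: int = 50
    min_identity: float = 0.9
    min_coverage: float = 0.9
    pairs_per_region: int = 3
    max_reported: int = 10

    def to_screen_params(self) -> ScreenParams:
        return ScreenParams(
            window=self.window,
            step=self.step,
            min_identity=self.min_identity,
            min_coverage=self.min_coverage,
            pairs_per_region=self.pairs_per_region,
            max_reported=self.max_reported,
        )


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "tephrimark_out"
    sim: SimConfig = field(default_factory=SimConfig)
    capture: CaptureParams = field(default_factory=CaptureParams)
    matrix: MatrixParams = field(default_factory=MatrixParams)
    trees: TreeParams = field(default_factory=TreeParams)
    pi: PiParams = field(default_factory=PiParams)
    diagnostics: DiagnosticsParams = field(default_factory=DiagnosticsParams)

    def stage_seed(self, stage: str) -> int:
        offsets = {"simulate": 1, "trees": 2, "diagnostics": 3}
        return int((self.seed * 7919 + offsets.get(stage, 0)) % (2**31))


_BLOCKS = {
    "sim": SimConfig,
    "capture": CaptureParams,
    "matrix": MatrixParams,
    "trees": TreeParams,
    "pi": PiParams,
    "diagnostics": DiagnosticsParams,
}


def _build(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in [{where}]: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            kwargs[name] = _build(cls, data.pop(name), name)
    top_known = {"seed", "outdir"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs.update(data)
    cfg = RunConfig(**kwargs)
    cfg.sim.seed = cfg.stage_seed("simulate")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        return config_from_dict(tomllib.load(fh))


def dump_resolved(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration snapshot alongside run outputs."""
    import json

    Path(path).write_text(json.dumps(asdict(cfg), indent=2, default=str) + "\n")
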