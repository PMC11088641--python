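"""Benchmark run configuration: YAML schema with strict validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from femurbench.constraints import METHOD_NAMES
from femurbench.loads import GaitFixtureParams
from femurbench.model import FemurParams
from femurbench.runner import DEFAULT_GEOMETRIES

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Fully resolved configuration of a benchmark run."""

    femur: FemurParams = field(default_factory=FemurParams)
    gait: GaitFixtureParams = field(default_factory=GaitFixtureParams)
    geometries: tuple = tuple(DEFAULT_GEOMETRIES)
    methods: tuple = METHOD_NAMES
    n_bins: int = 10
    exclusion_radius: float = 5.0
    method_options: dict = field(default_factory=dict)
    output_dir: str = "femurbench_out"
    seed: int = 0

    def validate(self) -> None:
        self.femur.validate()
        self.gait.validate()
        unknown = set(self.geometries) - set(DEFAULT_GEOMETRIES)
        if unknown:
            raise ValueError(f"unknown geometries: {sorted(unknown)}")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    def apply_seed(self) -> None:
        """Derive sub-seeds for the generator and the load fixture."""
        self.femur = dataclasses.replace(self.femur, rng_seed=int(self.seed) % 2**31)
        self.gait = dataclasses.replace(
            self.gait, rng_seed=(int(self.seed) + 1) % 2**31
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gait"].pop("muscles", None)  # muscle table is code-defined
        d["geometries"] = list(self.geometries)
        d["methods"] = list(self.methods)
        return d


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config: {sorted(unknown)}")
    femur = _build(FemurParams, data.pop("femur", {}) or {}, "femur")
    gait_data = data.pop("gait", {}) or {}
    if "muscles" in gait_data:
        raise ValueError("the muscle table is code-defined; remove 'muscles'")
    gait = _build(GaitFixtureParams, gait_data, "gait")
    cfg = RunConfig(femur=femur, gait=gait, **data)
    cfg.geometries = tuple(cfg.geometries)
    cfg.methods = tuple(cfg.methods)
    cfg.apply_seed()
    cfg.validate()
    return cfg
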