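"""Run configuration: one YAML-serializable object covering every stage.

The effective configuration of a run is always written next to its outputs,
so any artifact can be regenerated from its sidecar alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .phantom import (DegradationSpec, MisalignmentSpec, PhantomSpec,
                      TissueComponent)
from .regnet import RegNetConfig
from .synthesizer import SynthesizerConfig
from .training import ScheduleConfig, TrainConfig


@dataclass
class IOConfig:
    hu_min: float = -1000.0
    hu_max: float = 2200.0


@dataclass
class SimulateConfig:
    n: int = 200
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    misalignment: MisalignmentSpec = field(default_factory=MisalignmentSpec)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    io: IOConfig = field(default_factory=IOConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        out = cls()
        if "seed" in d:
            out.seed = int(d["seed"])
        if "out_dir" in d:
            out.out_dir = str(d["out_dir"])
        if "io" in d:
            out.io = IOConfig(**d["io"])
        if "simulate" in d:
            s = dict(d["simulate"])
            sim = SimulateConfig()
            if "n" in s:
                sim.n = int(s["n"])
            if "phantom" in s:
                p = dict(s["phantom"])
                if "components" in p:
                    p["components"] = [TissueComponent(**{
                        **c, "count": tuple(c["count"]),
                        "axes_frac": tuple(c["axes_frac"])})
                        for c in p["components"]]
                if "body_axes_frac" in p:
                    p["body_axes_frac"] = tuple(p["body_axes_frac"])
                sim.phantom = PhantomSpec(**p)
            if "degradation" in s:
                sim.degradation = DegradationSpec(**s["degradation"])
            if "misalignment" in s:
                sim.misalignment = MisalignmentSpec(**s["misalignment"])
            out.simulate = sim
        if "train" in d:
            t = dict(d["train"])
            if "weights" in t:
                t["weights"] = LossWeights(**t["weights"])
            if "synthesizer" in t:
                t["synthesizer"] = SynthesizerConfig(**t["synthesizer"])
            if "regnet" in t:
                r = dict(t["regnet"])
                r["down_filters"] = tuple(r["down_filters"])
                t["regnet"] = RegNetConfig(**r)
            out.train = TrainConfig(**t)
        if "schedule" in d:
            out.schedule = ScheduleConfig(**d["schedule"])
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
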