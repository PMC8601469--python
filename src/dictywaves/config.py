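"""Run configuration: a flat, file-round-trippable description of a run.

A :class:`RunConfig` bundles the lattice settings, the model parameters, the
run controls and an optional survey block (lists of densities and replicate
seeds).  It loads from YAML or JSON and serialises back losslessly, so every
output artifact can embed the exact configuration that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional

import yaml

from .params import ModelParams

__all__ = ["LatticeConfig", "RunBlock", "SurveyBlock", "RunConfig", "load_config"]


@dataclass
class LatticeConfig:
    N: int = 400
    phi1: float = 0.5
    phi2: float = 0.0
    seed: int = 0
    f_fire: float = 0.01
    u_fire: float = 1.0


@dataclass
class RunBlock:
    n_iter: int = 6000
    record_every: int = 60
    record_fields: bool = False
    seed: int = 0
    out: Optional[str] = None


@dataclass
class SurveyBlock:
    phi1: List[float] = field(default_factory=lambda: [0.5])
    phi2: List[float] = field(default_factory=lambda: [0.0])
    seeds: List[int] = field(default_factory=lambda: [0])


@dataclass
class RunConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    params: ModelParams = field(default_factory=ModelParams)
    run: RunBlock = field(default_factory=RunBlock)
    survey: SurveyBlock = field(default_factory=SurveyBlock)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"lattice", "params", "run", "survey"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")

        def build(klass, block):
            block = dict(block or {})
            names = {f for f in klass.__dataclass_fields__}
            bad = set(block) - names
            if bad:
                raise ValueError(
                    f"unknown keys {sorted(bad)} in {klass.__name__} block"
                )
            return klass(**block)

        return cls(
            lattice=build(LatticeConfig, d.get("lattice")),
            params=build(ModelParams, d.get("params")),
            run=build(RunBlock, d.get("run")),
            survey=build(SurveyBlock, d.get("survey")),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file (extension decides the format)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})
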