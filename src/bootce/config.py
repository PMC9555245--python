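"""Run configuration: one serialisable object covering every stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decision import DecisionRule
from .econ import EconParams
from .engine import GridSpec
from .inference import DesignSpec
from .trial import TrialGenConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = {
    "trial": TrialGenConfig,
    "design": DesignSpec,
    "econ": EconParams,
    "grid": GridSpec,
    "decision": DecisionRule,
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    Cross-field rules: every grid size must fit inside the generated trial,
    and the null scenario forces the economic model's zero-risk-reduction
    switch on.
    """

    trial: TrialGenConfig = field(default_factory=TrialGenConfig)
    design: DesignSpec = field(default_factory=DesignSpec)
    econ: EconParams = field(default_factory=EconParams)
    grid: GridSpec = field(default_factory=GridSpec)
    decision: DecisionRule = field(default_factory=DecisionRule)
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if max(self.grid.sizes) > self.trial.n_total:
            raise ValueError(
                f"largest grid size {max(self.grid.sizes)} exceeds "
                f"n_total {self.trial.n_total}"
            )
        if self.grid.scenario == "null" and not self.econ.null_effect:
            object.__setattr__(
                self, "econ", dataclasses.replace(self.econ, null_effect=True)
            )

    def to_dict(self) -> dict:
        d = {name: dataclasses.asdict(getattr(self, name))
             for name in _SECTIONS}
        d["grid"]["sizes"] = list(d["grid"]["sizes"])
        d["outdir"] = self.outdir
        d["log_level"] = self.log_level
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for name, typ in _SECTIONS.items():
            section = dict(d.get(name) or {})
            if name == "grid" and "sizes" in section:
                section["sizes"] = tuple(section["sizes"])
            kwargs[name] = typ(**section)
        return cls(**kwargs, outdir=d.get("outdir", "results"),
                   log_level=d.get("log_level", "INFO"))


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON — a YAML subset) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return RunConfig.from_dict(data)


def save_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
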