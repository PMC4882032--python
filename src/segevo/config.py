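"""Run configuration: one JSON-serializable object that, together with a
seed, reproduces a run exactly."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields, is_dataclass
from pathlib import Path

from .evolution import EvolutionConfig, MutationSpec
from .fitness import FitnessConfig
from .fly import TargetConfig
from .phasing import PhasingConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _build(cls, doc: dict):
    """Construct a (possibly nested) dataclass from a plain dict, rejecting
    unknown keys."""
    names = {f.name for f in fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown field(s) {sorted(unknown)}")
    return cls(**doc)


@dataclass
class RunConfig:
    """Everything a command-line run needs besides the seed.

    ``experiment`` selects the evolutionary scenario (``fly_to_mosquito``
    or ``lca_to_fly``); ``network_overrides`` patches individual kernel
    parameters of the shipped fly network, ``{module: {param: value}}``.
    """

    experiment: str = "fly_to_mosquito"
    seed: int = 0
    out_dir: str = "runs"
    n_bins: int = 200
    include_ftz: bool = True
    ftz_mode: str = "secondary"
    network_overrides: dict = field(default_factory=dict)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    phasing: PhasingConfig = field(default_factory=PhasingConfig)

    def __post_init__(self) -> None:
        if isinstance(self.evolution, dict):
            ev = dict(self.evolution)
            for key, sub in (("mutation", MutationSpec), ("fitness", FitnessConfig),
                             ("targets", TargetConfig)):
                if isinstance(ev.get(key), dict):
                    ev[key] = _build(sub, ev[key])
            self.evolution = _build(EvolutionConfig, ev)
        if isinstance(self.phasing, dict):
            self.phasing = _build(PhasingConfig, self.phasing)
        # keep the evolution-side flags consistent with the top level
        self.evolution.include_ftz = self.include_ftz
        self.evolution.ftz_mode = self.ftz_mode

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    doc = json.loads(Path(path).read_text())
    names = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - names
    if unknown:
        raise ValueError(f"config: unknown field(s) {sorted(unknown)}")
    return RunConfig(**doc)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.to_dict(), indent=1, default=str))
    return path
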