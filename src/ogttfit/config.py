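"""Hierarchical run configuration with full default coverage.

One YAML file drives the whole pipeline; every field has a documented
default and the config round-trips through serialization losslessly.
CLI flags override config values (CLI > file > defaults).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .fitting import OptimizerSettings
from .objective import CostWeights
from .params import FREE_PARAM_NAMES, FeasibleBox, default_box
from .solver import SolverSettings


class ConfigError(ValueError):
    """Unknown or malformed configuration content (fail-fast)."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with defaults for every field."""

    solver: SolverSettings = field(default_factory=lambda: SolverSettings(method="rk4"))
    weights: CostWeights = field(default_factory=CostWeights)
    box: FeasibleBox = field(default_factory=default_box)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    explore_budget: int = 100_000
    n_groups: int | str = "auto"
    n_restarts: int = 10
    seed: int = 0
    out_dir: str = "ogttfit_run"

    def to_dict(self) -> dict:
        d = {
            "solver": asdict(self.solver),
            "weights": asdict(self.weights),
            "box": {name: [float(lo), float(hi)] for name, lo, hi in
                    zip(FREE_PARAM_NAMES, self.box.lower, self.box.upper)},
            "cohort": asdict(self.cohort),
            "optimizer": asdict(self.optimizer),
            "explore_budget": self.explore_budget,
            "n_groups": self.n_groups,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        d["cohort"]["basal_G_range"] = list(d["cohort"]["basal_G_range"])
        d["cohort"]["basal_I_range"] = list(d["cohort"]["basal_I_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"solver", "weights", "box", "cohort", "optimizer",
                 "explore_budget", "n_groups", "n_restarts", "seed", "out_dir"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        for key, factory in (("solver", SolverSettings), ("weights", CostWeights),
                             ("optimizer", OptimizerSettings)):
            if key in d:
                sub = dict(d[key])
                names = {f.name for f in dataclasses.fields(factory)}
                bad = set(sub) - names
                if bad:
                    raise ConfigError(f"unknown {key} keys: {sorted(bad)}")
                kw[key] = factory(**sub)
        if "cohort" in d:
            sub = dict(d["cohort"])
            names = {f.name for f in dataclasses.fields(CohortSpec)}
            bad = set(sub) - names
            if bad:
                raise ConfigError(f"unknown cohort keys: {sorted(bad)}")
            for rk in ("basal_G_range", "basal_I_range"):
                if rk in sub:
                    sub[rk] = tuple(sub[rk])
            kw["cohort"] = CohortSpec(**sub)
        if "box" in d:
            bad = set(d["box"]) - set(FREE_PARAM_NAMES)
            if bad:
                raise ConfigError(f"unknown box parameters: {sorted(bad)}")
            base = default_box()
            kw["box"] = base.with_intervals(
                **{name: tuple(iv) for name, iv in d["box"].items()})
        for key in ("explore_budget", "n_groups", "n_restarts", "seed", "out_dir"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def content_hash(self) -> str:
        """Stable hash of the canonical serialized config (provenance)."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
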