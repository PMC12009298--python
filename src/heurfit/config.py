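"""Run configuration: one object bundling task, prior and estimator settings.

Round-trips losslessly through YAML or JSON, and its hash is embedded in every
output artifact so results are traceable to the exact settings that produced
them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .inference import FitConfig
from .models import PriorConfig
from .simulate import TaskConfig

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    task: TaskConfig = dataclasses.field(default_factory=TaskConfig)
    prior: PriorConfig = dataclasses.field(default_factory=PriorConfig)
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)
    n_boot: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["task"]["value_grid"] is not None:
            d["task"]["value_grid"] = list(d["task"]["value_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            task=TaskConfig(**d.get("task", {})),
            prior=PriorConfig(**d.get("prior", {})),
            fit=FitConfig(**d.get("fit", {})),
            n_boot=int(d.get("n_boot", 1000)),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (.yml/.yaml) or JSON."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return RunConfig.from_dict(data or {})
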