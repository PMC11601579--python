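"""Run configuration and manifests.

A :class:`RunConfig` is a single document controlling a full experiment:
task, network architecture, optimizer, reduction schedule, analysis settings,
output directory and root seed.  It round-trips losslessly through YAML, and
every CLI run writes a JSON manifest (config + seed + versions) sufficient to
reproduce its outputs.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import yaml

from .analysis import ClassifierConfig
from .network import NetworkSpec
from .reducer import ReductionSchedule
from .task import TaskConfig
from .trainer import TrainingConfig

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    schedule: ReductionSchedule = field(default_factory=ReductionSchedule)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_test_epochs: int = 100
    seed: int = 0
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        return {
            "task": asdict(self.task),
            "network": asdict(self.network),
            "training": asdict(self.training),
            "schedule": asdict(self.schedule),
            "classifier": asdict(self.classifier),
            "n_test_epochs": self.n_test_epochs,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        return cls(
            task=TaskConfig(**doc.pop("task", {})),
            network=NetworkSpec(**doc.pop("network", {})),
            training=TrainingConfig(**doc.pop("training", {})),
            schedule=ReductionSchedule(**doc.pop("schedule", {})),
            classifier=ClassifierConfig(**doc.pop("classifier", {})),
            **doc,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def write_manifest(directory, config: RunConfig, extra: dict | None = None) -> pathlib.Path:
    """Write a reproducibility manifest (config, seed, versions) as JSON."""
    import numpy

    from . import __version__

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "config": config.to_dict(),
        "versions": {"sahnet": __version__, "numpy": numpy.__version__},
    }
    if extra:
        doc.update(extra)
    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return path
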