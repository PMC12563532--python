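"""Experiment configuration with YAML round-trip.

An :class:`ExperimentConfig` bundles the dataset recipe (or a path to data
on disk), the labeled fraction, the training hyperparameters and the seed
list for replicated runs. ``parse(serialize(config)) == config`` holds
exactly, so every run can be reconstructed from the config file it writes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .capr import FocalConfig
from .contrastive import ContrastiveConfig
from .data import PerturbProfile, SyntheticDatasetSpec
from .trainer import TrainConfig

__all__ = ["ExperimentConfig", "ABLATION_GRID", "ablation_config"]

# The four incremental configurations plus the supervised baseline:
# (consistency regularization, contrastive module, pseudo-label module)
ABLATION_GRID: dict[str, tuple[bool, bool, bool]] = {
    "baseline": (False, False, False),
    "mt": (True, False, False),
    "mt+sde": (True, True, False),
    "mt+capr": (True, False, True),
    "full": (True, True, True),
}


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, serializable to a YAML file."""

    dataset: SyntheticDatasetSpec = field(default_factory=SyntheticDatasetSpec)
    data_path: str | None = None  # overrides `dataset` when set
    label_fraction: float = 0.2
    train: TrainConfig = field(default_factory=TrainConfig)
    seeds: tuple[int, ...] = (0, 1, 2)
    output_dir: str = "runs"

    def __post_init__(self):
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in (0, 1]")
        if not self.seeds:
            raise ValueError("at least one seed is required")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seeds"] = list(self.seeds)
        d["dataset"]["counts"] = (
            list(self.dataset.counts) if self.dataset.counts is not None else None)
        d["train"]["hidden"] = list(self.train.hidden)
        return d

    def serialize(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        ds = dict(d.pop("dataset", {}))
        if ds.get("counts") is not None:
            ds["counts"] = tuple(ds["counts"])
        tr = dict(d.pop("train", {}))
        if "hidden" in tr:
            tr["hidden"] = tuple(tr["hidden"])
        for key, sub in (("focal", FocalConfig), ("contrastive", ContrastiveConfig),
                         ("perturb", PerturbProfile)):
            if key in tr and isinstance(tr[key], dict):
                tr[key] = sub(**tr[key])
        if "seeds" in d:
            d["seeds"] = tuple(d["seeds"])
        try:
            return cls(dataset=SyntheticDatasetSpec(**ds),
                       train=TrainConfig(**tr), **d)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc

    @classmethod
    def parse(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def load(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.parse(fh.read())

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.serialize())


def ablation_config(config: ExperimentConfig, variant: str) -> ExperimentConfig:
    """Derive one row of the ablation grid from a base experiment config."""
    try:
        cons, sde, capr = ABLATION_GRID[variant]
    except KeyError:
        raise ValueError(
            f"unknown ablation variant {variant!r}; choose from {list(ABLATION_GRID)}")
    train = replace(config.train, use_consistency=cons, use_sde=sde, use_capr=capr)
    return replace(config, train=train)
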