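"""Pipeline configuration: a fully-serialisable YAML round-trippable spec."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .delineate import CtRuleSpec, ThresholdSpec
from .phantom import (
    GroupPerturbationModel,
    PhantomSpec,
    VariantPerturbationModel,
    default_group_perturbations,
)

__all__ = ["PipelineConfig"]


def _asdict(obj):
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _tupled(cls, d: dict):
    fields = {f.name: f.type for f in dataclasses.fields(cls)}
    kw = {}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        kw[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kw)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, serialisable to/from YAML."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    perturbations: dict[str, GroupPerturbationModel] = field(
        default_factory=default_group_perturbations
    )
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    ct_rule: CtRuleSpec = field(default_factory=CtRuleSpec)
    n_a: int = 32
    n_b: int = 24
    n_c: int = 16
    seed: int = 0
    holm: bool = False
    save_volumes: bool = False
    save_masks: bool = True
    outdir: str = "gtvconcord_out"

    def to_dict(self) -> dict:
        return {
            "phantom": _asdict(self.phantom),
            "perturbations": {
                g: {
                    "gtv_3d": _asdict(m.gtv_3d),
                    "gtv_pet_ref": _asdict(m.gtv_pet_ref),
                    "gtv_pet_reg": _asdict(m.gtv_pet_reg),
                }
                for g, m in self.perturbations.items()
            },
            "threshold": _asdict(self.threshold),
            "ct_rule": _asdict(self.ct_rule),
            "n_a": self.n_a, "n_b": self.n_b, "n_c": self.n_c,
            "seed": self.seed, "holm": self.holm,
            "save_volumes": self.save_volumes, "save_masks": self.save_masks,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "phantom" in kw:
            kw["phantom"] = _tupled(PhantomSpec, kw["phantom"])
        if "perturbations" in kw:
            kw["perturbations"] = {
                g: GroupPerturbationModel(
                    **{k: _tupled(VariantPerturbationModel, v) for k, v in m.items()}
                )
                for g, m in kw["perturbations"].items()
            }
        if "threshold" in kw:
            kw["threshold"] = _tupled(ThresholdSpec, kw["threshold"])
        if "ct_rule" in kw:
            kw["ct_rule"] = _tupled(CtRuleSpec, kw["ct_rule"])
        return cls(**kw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, logged into every output."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
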