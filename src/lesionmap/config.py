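"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .delineation import DelineationParams
from .synthetic import CohortConfig, EffectSpec


@dataclass
class VlomSettings:
    n_perm: int = 5000
    cluster_forming_p: float = 0.001
    connectivity: int = 26
    min_per_cell: int = 10
    mode: str = "split_by_laterality"


@dataclass
class VolumetricsSettings:
    n_perm: int = 100_000
    q: float = 0.05
    equal_var: bool = True


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: stage parameters plus the
    master seed. Serializes to YAML and reloads to an equal value."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    delineation: DelineationParams = field(default_factory=DelineationParams)
    volumetrics: VolumetricsSettings = field(default_factory=VolumetricsSettings)
    vlom: VlomSettings = field(default_factory=VlomSettings)

    def to_yaml(self, path: str | Path | None = None) -> str:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        text = yaml.safe_dump(listify(dataclasses.asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        source_str = str(source)
        if "\n" in source_str:
            text = source_str  # inline YAML document
        else:
            text = Path(source_str).read_text()
        raw = yaml.safe_load(text)
        cohort_raw = raw.get("cohort", {})
        effects = EffectSpec(**cohort_raw.pop("effects", {}))
        extent_params = {
            k: tuple(v) for k, v in cohort_raw.pop("extent_params", {}).items()
        }
        cohort = CohortConfig(effects=effects, **cohort_raw)
        if extent_params:
            cohort.extent_params = extent_params
        cohort.grid_shape = tuple(cohort.grid_shape)
        return cls(
            seed=raw.get("seed", 0),
            cohort=cohort,
            delineation=DelineationParams(**raw.get("delineation", {})),
            volumetrics=VolumetricsSettings(**raw.get("volumetrics", {})),
            vlom=VlomSettings(**raw.get("vlom", {})),
        )
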