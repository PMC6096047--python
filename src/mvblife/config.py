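"""Run configuration: one structured YAML file collecting every analysis
constant (feature count, shuffle repetitions, evidence and outlier
thresholds, prior type, seeds) with schema validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec, NoiseSpec

__all__ = ["Thresholds", "RunConfig", "load_config"]


@dataclass
class Thresholds:
    evidence: float = 3.0        # nats, model-comparison boost/reduction
    decodability: float = 3.0    # nats, real - shuffled inclusion rule
    top_voxel_z: float = 2.0     # SDs, top-weighted voxel definition
    outlier_z: float = 5.0       # SDs, group-level trimming

    def validate(self) -> None:
        for name, v in dataclasses.asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    paradigm: str = "LTM"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    data_dir: str | None = None          # ingest a saved cohort instead
    k_features: int = 1000
    prior_type: str = "sparse"
    fwhm_mm: float = 8.0
    shuffle_reps: int = 20
    thresholds: Thresholds = field(default_factory=Thresholds)
    exclusion_policy: str = "any"        # "any" | "both" ROI decodability failure
    contrast: str | None = None          # default: by paradigm
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        self.cohort.paradigm = self.paradigm
        if self.contrast is None:
            self.contrast = ("subsequent_memory" if self.paradigm == "LTM"
                             else "load_linear")

    def validate(self) -> None:
        self.thresholds.validate()
        if self.k_features < 1:
            raise ValueError("k_features must be >= 1")
        if self.shuffle_reps < 0:
            raise ValueError("shuffle_reps must be >= 0")
        if self.prior_type not in ("sparse", "smooth"):
            raise ValueError("prior_type must be 'sparse' or 'smooth'")
        if self.exclusion_policy not in ("any", "both"):
            raise ValueError("exclusion_policy must be 'any' or 'both'")
        self.cohort.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if not isinstance(d["cohort"]["scenario"], str):
            d["cohort"]["scenario"] = "<callable>"
        d["cohort"].pop("memory_prob_fn", None)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return data


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw = _build(RunConfig, raw, str(path))
    if "cohort" in raw:
        c = _build(CohortSpec, raw["cohort"], str(path))
        if "noise" in c:
            c["noise"] = NoiseSpec(**_build(NoiseSpec, c["noise"], str(path)))
        if "age_range" in c:
            c["age_range"] = tuple(c["age_range"])
        raw["cohort"] = CohortSpec(**c)
    if "thresholds" in raw:
        raw["thresholds"] = Thresholds(**_build(Thresholds, raw["thresholds"],
                                                str(path)))
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
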