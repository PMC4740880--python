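"""Pipeline configuration: thresholds, seeds, stage toggles, provenance."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import riphewas

ALL_STAGES = ("simulate", "annotate", "score", "cnv", "scan", "human_phewas")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the published analysis values."""

    seed: int = 0
    out_dir: str = "riphewas_out"
    stages: tuple[str, ...] = ALL_STAGES

    # PheWAS
    q_threshold: float = 0.01
    map_window_bp: int = 1_000_000

    # CNV
    cnv_alpha: float = 1e-6
    cnv_min_consec: int = 10
    cnv_min_bp: int = 1000
    cnv_window_bp: int = 100

    # clinical arm
    min_code_count: int = 2
    min_individuals: int = 20
    maf_min: float = 0.01
    bonferroni_alpha: float = 0.05

    # simulation scale
    n_strains: int = 80
    n_markers: int = 120
    n_traits: int = 60
    n_genes: int = 12
    n_individuals: int = 2000
    depth_mean: float = 30.0
    genome_length_bp: int = 200_000

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the global seed."""
        idx = ALL_STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed).spawn(len(ALL_STAGES))[idx]
        return int(ss.generate_state(1)[0])

    def provenance(self) -> dict:
        return {
            "config": {**asdict(self), "stages": list(self.stages)},
            "versions": {
                "riphewas": riphewas.__version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
            },
        }

    def write_provenance(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance(), fh, indent=2, sort_keys=True)
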