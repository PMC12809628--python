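"""Pipeline configuration: paths, thresholds, seeds, and model choices."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input artifacts (populated by `simulate` when running synthetically)
    activities_csv: str | None = None
    residue_table: str | None = None
    zscale_table: str | None = None  # None -> packaged Sandberg fixture
    blocklist: str | None = None

    scheme: str = "morgan"  # morgan | maccs | physchem
    algorithm: str = "rf"  # svm | rf | xgb
    seed: int = 1
    run_seeds: list[int] = field(default_factory=lambda: [1, 2, 3])
    split_fraction: float = 0.7
    sem_threshold: float = 0.3
    outlier_threshold: float = 2.0
    conflict_tolerance: float = 0.5
    grid: str | dict | None = None  # None = fixed hyperparameters
    hyperparameters: dict | None = None
    group_cv_by_molecule: bool = False

    # synthetic-data generation (the `simulate` stage)
    n_scaffolds: int = 25
    series_size: int = 30

    def validate(self) -> None:
        for name in ("sem_threshold", "outlier_threshold", "conflict_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.scheme not in ("morgan", "maccs", "physchem"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.algorithm not in ("svm", "rf", "xgb"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
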