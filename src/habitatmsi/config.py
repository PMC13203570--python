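"""Run configuration: one YAML document drives the whole pipeline.

A single ``master_seed`` is the only source of randomness; every stage
derives its own seed from it by hashing the stage name, so stages are
reproducible independently and never share a stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class HabitatParams:
    k: int = 6
    k_candidates: tuple[int, ...] = (4, 6, 8)
    voxels_per_sp: int = 300
    compactness: float = 1e-2
    perplexity: float = 30.0
    tsne_max_iter: int = 1000
    kmeans_max_iter: int = 100
    kmeans_replicates: int = 10
    pooled: bool = False  # fit on all patients instead of training only


@dataclass
class RiskParams:
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_repeats: int = 100
    fraction: float = 0.8
    metric: str = "spearman"
    algorithm: str = "kmedoids"
    pooled: bool = False


@dataclass
class ModelParams:
    penalty: float | str = "cv"
    horizon: float = 60.0
    n_boot: int = 200


@dataclass
class PreprocessConf:
    erosion_radius: int = 1
    crop_margin: int = 2
    entropy_window_radius: int = 2
    entropy_bins: int = 32


@dataclass
class RunConfig:
    run_dir: str = "runs/default"
    master_seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    preprocess: PreprocessConf = field(default_factory=PreprocessConf)
    habitat: HabitatParams = field(default_factory=HabitatParams)
    msi_connectivity: int = 6
    risk: RiskParams = field(default_factory=RiskParams)
    models: ModelParams = field(default_factory=ModelParams)
    train_fraction: float = 0.75  # 3:1 split
    stratify_split: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("habitat", "risk"):
            for f_ in ("k_candidates", "k_range"):
                if f_ in d[key]:
                    d[key][f_] = list(d[key][f_])
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConf(**d["preprocess"])
        if "habitat" in d:
            h = dict(d["habitat"])
            if "k_candidates" in h:
                h["k_candidates"] = tuple(h["k_candidates"])
            d["habitat"] = HabitatParams(**h)
        if "risk" in d:
            r = dict(d["risk"])
            if "k_range" in r:
                r["k_range"] = tuple(r["k_range"])
            d["risk"] = RiskParams(**r)
        if "models" in d:
            d["models"] = ModelParams(**d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
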