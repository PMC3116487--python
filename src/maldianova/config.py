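"""Pipeline configuration: one flat-ish YAML document, one root seed.

Every tunable of the work-flow lives here with its documented default;
stage-level seeds are derived deterministically from the root seed so a
single integer reproduces a whole run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

STAGES = ("simulate", "preprocess", "anova", "cluster", "select", "classify")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(root_seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulate
    axis_length: int = 4000
    n_families: int = 5
    peaks_per_family: int = 4
    n_singletons: int = 10
    family_correlation: float = 0.9
    # preprocess
    log_guard: float = 1.0
    smooth_window: int = 9
    struct_width: int = 151
    align: bool = True
    align_window: int = 30
    quant_window: int = 4
    cwt_scale_min: int = 3
    cwt_scale_max: int = 16
    cwt_length_min: int = 7
    cwt_noise_quantile: float = 0.95
    cwt_min_snr: float = 3.0
    pseudo_count: float = 0.1
    offset: float = 0.0
    # anova / cluster
    alpha: float = 0.05
    week_categorical: bool = True
    cut_distance: float = 0.3
    # selection / classification
    target_factor: str = "diet"
    feature_sizes: tuple[int, ...] = (3, 5, 8)
    folds: int = 10
    n_random: int = 1000
    aco_ants: int = 200
    aco_iterations: int = 100
    aco_evaporation: float = 0.1
    extra: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_sizes"] = list(self.feature_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = [k for k in d if k not in known]
        if unknown:
            raise KeyError(f"unknown config key(s): {unknown}")
        if "feature_sizes" in d:
            d["feature_sizes"] = tuple(d["feature_sizes"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
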