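"""Run configuration: schema-validated nested sections, YAML round-trip.

Defaults are the printed study values wherever they exist (filter cutoff,
thresholds, constraint weights, curriculum parameters, optimizer settings);
unknown keys are rejected so typos fail loudly.  Every artifact the pipeline
writes embeds the hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .constraints import ConstraintConfig
from .model import ModelConfig
from .schedule import CurriculumConfig
from .train_eval import TrainConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Section):
    n_subjects: int = 5
    cycles_per_level: int = 12
    seed: int = 0
    asymmetry_gain: float = 1.0
    variability_gain: float = 0.02
    easy: bool = False


class PreprocessSection(_Section):
    lowpass_cutoff_hz: float = 20.0
    lowpass_order: int = 4
    filter_alpha: float = 0.98
    outlier_z_thresh: float = 3.5
    outlier_max_gap: int = 4


class SegmentSection(_Section):
    rise_thresh_n: float = 20.0
    fall_thresh_n: float = 30.0
    duration_min_s: float = 0.4
    duration_max_s: float = 1.2
    peak_force_min_bw: float = 0.8


class ModelSection(_Section):
    profile: str = "tiny"  # "tiny" | "paper"
    dropout: float = 0.1
    mc_passes: int = 30


class ConstraintSection(_Section):
    smoothness_kappa: float = 0.1
    kappa1: float = 0.5
    kappa2: float = 0.3
    sym_beta: float = 0.15
    sym_eps: float = 1e-6
    dissipation_init: float = 0.05


class CurriculumSection(_Section):
    base_weights: tuple[float, float, float, float] = (0.1, 0.15, 0.08, 0.12)
    warmup_epochs: int = 20
    ramp_epochs: int = 80
    fatigue_gain: float = 0.15


class TrainSection(_Section):
    lr: float = 3e-3
    weight_decay: float = 1e-5
    epochs: int = 30
    batch_size: int = 16
    grad_clip: float = 1.0
    seed: int = 0
    val_fraction: float = 0.25


class RunConfig(_Section):
    data: DataSection = DataSection()
    preprocess: PreprocessSection = PreprocessSection()
    segment: SegmentSection = SegmentSection()
    model: ModelSection = ModelSection()
    constraints: ConstraintSection = ConstraintSection()
    curriculum: CurriculumSection = CurriculumSection()
    train: TrainSection = TrainSection()

    # ------------------------------------------------------------ conversions
    def model_cfg(self) -> ModelConfig:
        base = ModelConfig.tiny() if self.model.profile == "tiny" else ModelConfig()
        base.dropout = self.model.dropout
        base.mc_passes = self.model.mc_passes
        return base

    def constraint_cfg(self) -> ConstraintConfig:
        c = self.constraints
        return ConstraintConfig(
            smoothness_kappa=c.smoothness_kappa, kappa1=c.kappa1, kappa2=c.kappa2,
            sym_beta=c.sym_beta, sym_eps=c.sym_eps, dissipation_init=c.dissipation_init,
        )

    def curriculum_cfg(self) -> CurriculumConfig:
        c = self.curriculum
        return CurriculumConfig(
            base_weights=tuple(c.base_weights), warmup_epochs=c.warmup_epochs,
            ramp_epochs=c.ramp_epochs, fatigue_gain=c.fatigue_gain,
        )

    def train_cfg(self) -> TrainConfig:
        t = self.train
        return TrainConfig(
            lr=t.lr, weight_decay=t.weight_decay, epochs=t.epochs,
            batch_size=t.batch_size, grad_clip=t.grad_clip, seed=t.seed,
            val_fraction=t.val_fraction,
        )

    # -------------------------------------------------------------- round-trip
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]
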