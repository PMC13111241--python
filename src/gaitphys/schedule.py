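"""Adaptive constraint weighting: curriculum alpha(e), fatigue beta(y_f).

Effective weight of constraint i at epoch e and fatigue level y_f is the
separable product lambda_i = lambda_i^0 * alpha(e) * beta(y_f).  The
curriculum keeps constraints at a 0.1 floor during warmup, ramps linearly to
1.0 over the ramp window, then holds; the fatigue factor amplifies
enforcement linearly with the (true or predicted) fatigue level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONSTRAINT_NAMES = ("kinematic", "dynamic", "symmetry", "energy")


@dataclass
class CurriculumConfig:
    # base weights for (kinematic, dynamic, symmetry, energy)
    base_weights: tuple[float, float, float, float] = (0.1, 0.15, 0.08, 0.12)
    warmup_epochs: int = 20
    ramp_epochs: int = 80
    fatigue_gain: float = 0.15  # gamma
    warmup_floor: float = 0.1

    def __post_init__(self):
        if self.warmup_epochs < 0 or self.ramp_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if any(w < 0 for w in self.base_weights) or self.fatigue_gain < 0:
            raise ValueError("weights and gain must be non-negative")


def curriculum_alpha(epoch: int, cfg: CurriculumConfig) -> float:
    """Piecewise-linear curriculum: floor, linear ramp, then 1.0."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    floor = cfg.warmup_floor
    if epoch < cfg.warmup_epochs:
        return floor
    if cfg.ramp_epochs == 0 or epoch >= cfg.warmup_epochs + cfg.ramp_epochs:
        return 1.0
    return floor + (1.0 - floor) * (epoch - cfg.warmup_epochs) / cfg.ramp_epochs


def fatigue_beta(y_f: int | float, cfg: CurriculumConfig) -> float:
    """State-dependent scaling beta = 1 + gamma * y_f for levels 0..4."""
    if not 0 <= y_f <= 4:
        raise ValueError(f"fatigue level {y_f} outside 0..4")
    return 1.0 + cfg.fatigue_gain * float(y_f)


def effective_weights(epoch: int, y_f: int | float, cfg: CurriculumConfig) -> np.ndarray:
    """lambda_i(e, y_f) = lambda_i^0 * alpha(e) * beta(y_f), i = 1..4."""
    a = curriculum_alpha(epoch, cfg)
    b = fatigue_beta(y_f, cfg)
    return np.asarray(cfg.base_weights, dtype=float) * a * b
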