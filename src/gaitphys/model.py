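"""Hierarchical attention network with biomechanical heads.

Pipeline: per-sensor convolutional embedding + learnable anatomical position
encodings -> multi-head self-attention across the sensor axis (cross-sensor
fusion) -> parallel temporal pathways (residual dilated causal convolutions
and a pre-norm transformer) merged by a learned sigmoid gate -> biomechanical
heads (joint angles, ground reaction force, COM velocity, auxiliary energy)
and task heads (5-class fatigue softmax via mean pooling + MLP; asymmetry
regression via max pooling + linear, with a log-variance head for the
heteroscedastic likelihood).  Monte-Carlo dropout provides epistemic
uncertainty at inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Tensor,
    concatenate,
    conv1d_causal,
    dropout,
    layer_norm,
    softmax,
    stack,
)


@dataclass
class ModelConfig:
    n_sensors: int = 8
    n_channels: int = 9
    embed_dim_sensor: int = 64
    fusion_heads: int = 8
    temporal_dim: int = 256
    temporal_heads: int = 8
    conv_blocks: int = 6
    dilations: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    kernel: int = 3
    transformer_layers: int = 4
    n_classes: int = 5
    asym_dim: int = 6
    dropout: float = 0.1
    mc_passes: int = 30
    mlp_widths: tuple[int, ...] = (256, 128, 64)
    theta_scale: float = 2.5  # rad; generously super-anatomical so the
    # kinematic hinge stays active within the head's range
    dissipation_init: float = 0.05

    def __post_init__(self):
        if self.embed_dim_sensor % self.fusion_heads:
            raise ValueError("embed_dim_sensor must be divisible by fusion_heads")
        if self.temporal_dim % self.temporal_heads:
            raise ValueError("temporal_dim must be divisible by temporal_heads")
        if len(self.dilations) != self.conv_blocks:
            raise ValueError("need one dilation per conv block")

    @classmethod
    def tiny(cls) -> "ModelConfig":
        """Desk-scale profile used by the synthetic smoke experiments."""
        return cls(
            embed_dim_sensor=16,
            fusion_heads=4,
            temporal_dim=32,
            temporal_heads=4,
            transformer_layers=1,
            mlp_widths=(64, 32),
        )


@dataclass
class Prediction:
    class_probs: np.ndarray  # (B, 5)
    fatigue_argmax: np.ndarray  # (B,)
    asym_mean: np.ndarray  # (B, M)
    asym_var: np.ndarray  # (B, M)
    attention_maps: np.ndarray | None = None  # (B, N, N) sensor attention


def _glorot(rng, *shape):
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)


def _small(rng, *shape):
    return Tensor(rng.normal(0.0, 0.03, shape), requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape):
    return Tensor(np.ones(shape), requires_grad=True)


class GaitFatigueNet:
    """The physics-informed hierarchical attention model."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        d = cfg.embed_dim_sensor
        dt = cfg.temporal_dim
        # sensor embedding: shared kernel-3 conv + per-slot position encodings
        p["emb_w"] = _glorot(rng, cfg.kernel, cfg.n_channels, d)
        p["emb_b"] = _zeros(d)
        p["pos_enc"] = Tensor(rng.normal(0, 0.02, (cfg.n_sensors, d)), requires_grad=True)
        for nm in ("q", "k", "v", "o"):
            p[f"fus_{nm}"] = _glorot(rng, d, d)
        p["fus_ln1_g"], p["fus_ln1_b"] = _ones(d), _zeros(d)
        p["fus_ff1"], p["fus_ff1_b"] = _glorot(rng, d, 2 * d), _zeros(2 * d)
        p["fus_ff2"], p["fus_ff2_b"] = _glorot(rng, 2 * d, d), _zeros(d)
        p["fus_ln2_g"], p["fus_ln2_b"] = _ones(d), _zeros(d)
        p["proj_w"], p["proj_b"] = _glorot(rng, d, dt), _zeros(dt)
        for b in range(cfg.conv_blocks):
            p[f"conv{b}_w"] = _glorot(rng, cfg.kernel, dt, dt)
            p[f"conv{b}_b"] = _zeros(dt)
        for l in range(cfg.transformer_layers):
            for nm in ("q", "k", "v", "o"):
                p[f"tr{l}_{nm}"] = _glorot(rng, dt, dt)
            p[f"tr{l}_ln1_g"], p[f"tr{l}_ln1_b"] = _ones(dt), _zeros(dt)
            p[f"tr{l}_ff1"], p[f"tr{l}_ff1_b"] = _glorot(rng, dt, 2 * dt), _zeros(2 * dt)
            p[f"tr{l}_ff2"], p[f"tr{l}_ff2_b"] = _glorot(rng, 2 * dt, dt), _zeros(dt)
            p[f"tr{l}_ln2_g"], p[f"tr{l}_ln2_b"] = _ones(dt), _zeros(dt)
        p["gate_w"], p["gate_b"] = _glorot(rng, 2 * dt, dt), _zeros(dt)
        # biomech heads start near zero so constraint terms begin feasible
        p["head_theta_w"], p["head_theta_b"] = _small(rng, dt, 6), _zeros(6)
        p["head_fg_w"], p["head_fg_b"] = _small(rng, dt, 3), _zeros(3)
        p["head_vc_w"], p["head_vc_b"] = _small(rng, dt, 3), _zeros(3)
        p["head_e_w"], p["head_e_b"] = _small(rng, dt, 1), _zeros(1)
        widths = (dt,) + cfg.mlp_widths + (cfg.n_classes,)
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            p[f"mlp{i}_w"], p[f"mlp{i}_b"] = _glorot(rng, a, b), _zeros(b)
        self.n_mlp = len(widths) - 1
        p["reg_w"], p["reg_b"] = _small(rng, dt, cfg.asym_dim), _zeros(cfg.asym_dim)
        p["logvar_w"], p["logvar_b"] = _small(rng, dt, cfg.asym_dim), _zeros(cfg.asym_dim)
        p["dissipation_c"] = Tensor(cfg.dissipation_init, requires_grad=True)
        self.params = p

    # ------------------------------------------------------------------ utils
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def weight_parameters(self) -> list[Tensor]:
        """Parameters subject to L2 regularization (matrices, not biases/gains)."""
        return [v for k, v in self.params.items() if v.data.ndim >= 2]

    def _mha(self, h: Tensor, prefix: str, heads: int, mask: np.ndarray | None, axis_batchdims: int):
        """Multi-head self-attention over the second-to-last axis of ``h``."""
        p = self.params
        n = h.shape[-2]
        dm = h.shape[-1]
        dh = dm // heads
        lead = h.shape[:-2]

        def _split(x):
            x = x.reshape(*lead, n, heads, dh)
            return x.swapaxes(-2, -3)  # (..., heads, n, dh)

        q = _split(h @ p[f"{prefix}_q"])
        k = _split(h @ p[f"{prefix}_k"])
        v = _split(h @ p[f"{prefix}_v"])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        if mask is not None:
            bias = np.where(mask, 0.0, -1e9)  # (n,) over keys
            scores = scores + Tensor(bias)
        att = softmax(scores, axis=-1)
        out = att @ v  # (..., heads, n, dh)
        out = out.swapaxes(-2, -3).reshape(*lead, n, dm)
        return out @ p[f"{prefix}_o"], att

    def _conv_same(self, x: Tensor, w: Tensor, b: Tensor) -> Tensor:
        """Kernel-3 'same' convolution along the time axis."""
        t_len = x.shape[-2]
        xp = x.pad_axis(-2, 1, 1)
        out = None
        for j in range(3):
            sl = [slice(None)] * x.ndim
            sl[-2] = slice(j, j + t_len)
            term = xp[tuple(sl)] @ w[j]
            out = term if out is None else out + term
        return out + b

    # ---------------------------------------------------------------- stages
    def sensor_fusion(self, x: np.ndarray, mask: np.ndarray | None = None):
        """(B, T, N, C) -> fused (B, T, d) plus sensor-attention weights."""
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite sensor input")
        p = self.params
        xt = Tensor(x)
        h = xt.swapaxes(1, 2)  # (B, N, T, C)
        h = self._conv_same(h, p["emb_w"], p["emb_b"])  # (B, N, T, d)
        h = h.swapaxes(1, 2)  # (B, T, N, d)
        h = h + p["pos_enc"]
        attn_out, att = self._mha(h, "fus", self.cfg.fusion_heads, mask, 2)
        h = layer_norm(h + attn_out, p["fus_ln1_g"], p["fus_ln1_b"])
        ff = ((h @ p["fus_ff1"] + p["fus_ff1_b"]).tanh()) @ p["fus_ff2"] + p["fus_ff2_b"]
        h = layer_norm(h + ff, p["fus_ln2_g"], p["fus_ln2_b"])
        if mask is not None:
            m = mask.astype(float)
            h = h * Tensor(m.reshape(1, 1, -1, 1))
            z0 = h.sum(axis=2) * (1.0 / m.sum())
        else:
            z0 = h.mean(axis=2)
        return z0, att

    def temporal_extract(self, z0: Tensor, gate_mode: str = "learned") -> Tensor:
        """(B, T, d) -> (B, T, D): gated merge of conv and transformer paths."""
        p = self.params
        h0 = z0 @ p["proj_w"] + p["proj_b"]
        hc = h0
        for b, dil in enumerate(self.cfg.dilations[: self.cfg.conv_blocks]):
            hc = hc + conv1d_causal(hc, p[f"conv{b}_w"], p[f"conv{b}_b"], dilation=dil).tanh()
        ht = h0
        for l in range(self.cfg.transformer_layers):
            hn = layer_norm(ht, p[f"tr{l}_ln1_g"], p[f"tr{l}_ln1_b"])
            attn_out, _ = self._mha(hn, f"tr{l}", self.cfg.temporal_heads, None, 1)
            ht = ht + attn_out
            hn = layer_norm(ht, p[f"tr{l}_ln2_g"], p[f"tr{l}_ln2_b"])
            ff = ((hn @ p[f"tr{l}_ff1"] + p[f"tr{l}_ff1_b"]).tanh()) @ p[f"tr{l}_ff2"] + p[f"tr{l}_ff2_b"]
            ht = ht + ff
        if gate_mode == "conv":
            return hc
        if gate_mode == "transformer":
            return ht
        g = (concatenate([hc, ht], axis=-1) @ p["gate_w"] + p["gate_b"]).sigmoid()
        return g * hc + (g * (-1.0) + 1.0) * ht

    def conv_pathway(self, z0: Tensor) -> Tensor:
        return self.temporal_extract(z0, gate_mode="conv")

    def biomech_heads(self, z1: Tensor) -> dict[str, Tensor]:
        p = self.params
        theta = (z1 @ p["head_theta_w"] + p["head_theta_b"]).tanh() * self.cfg.theta_scale
        f_g = z1 @ p["head_fg_w"] + p["head_fg_b"]
        v_c = z1 @ p["head_vc_w"] + p["head_vc_b"]
        e_aux = (z1 @ p["head_e_w"] + p["head_e_b"])[..., 0]
        return {"theta": theta, "f_g": f_g, "v_c": v_c, "e_aux": e_aux}

    def task_heads(self, z1: Tensor, rng: np.random.Generator | None = None,
                   dropout_on: bool = False) -> dict[str, Tensor]:
        p = self.params
        rng = rng or np.random.default_rng(0)
        pooled = z1.mean(axis=1)
        h = pooled
        for i in range(self.n_mlp):
            h = h @ p[f"mlp{i}_w"] + p[f"mlp{i}_b"]
            if i < self.n_mlp - 1:
                h = h.tanh()
                h = dropout(h, self.cfg.dropout, rng, dropout_on)
        probs = softmax(h, axis=-1)
        pooled_max = z1.amax(axis=1)
        pooled_max = dropout(pooled_max, self.cfg.dropout, rng, dropout_on)
        asym = pooled_max @ p["reg_w"] + p["reg_b"]
        logvar = (pooled_max @ p["logvar_w"] + p["logvar_b"]).tanh() * 4.0
        return {"logits": h, "class_probs": probs, "asym": asym, "logvar": logvar}

    # ---------------------------------------------------------------- forward
    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        dropout_on: bool = False,
        gate_mode: str = "learned",
    ) -> dict[str, Tensor]:
        z0, att = self.sensor_fusion(x, mask=mask)
        z1 = self.temporal_extract(z0, gate_mode=gate_mode)
        out = self.biomech_heads(z1)
        out.update(self.task_heads(z1, rng=rng, dropout_on=dropout_on))
        out["z1"] = z1
        out["sensor_attention"] = att
        return out

    def predict(
        self,
        x: np.ndarray,
        mask: np.ndarray | None = None,
        mc_passes: int | None = None,
        dropout_on: bool = True,
        seed: int = 0,
    ) -> Prediction:
        """Monte-Carlo-dropout prediction: K stochastic passes, mean/variance."""
        k = self.cfg.mc_passes if mc_passes is None else mc_passes
        if dropout_on and self.cfg.dropout > 0 and k < 2:
            raise ValueError("MC-dropout variance needs at least 2 passes")
        rng = np.random.default_rng(seed)
        asyms, probs = [], []
        att = None
        for _ in range(max(k, 1)):
            out = self.forward(x, mask=mask, rng=rng, dropout_on=dropout_on)
            asyms.append(out["asym"].data)
            probs.append(out["class_probs"].data)
            att = out["sensor_attention"].data
            out["class_probs"].free_graph()
            out["asym"].free_graph()
        a = np.stack(asyms)
        mean_p = np.mean(probs, axis=0)
        att_map = att.mean(axis=(1, 2)) if att is not None else None  # (B, N, N)
        return Prediction(
            class_probs=mean_p,
            fatigue_argmax=np.argmax(mean_p, axis=-1),
            asym_mean=a.mean(axis=0),
            asym_var=a.var(axis=0),
            attention_maps=att_map,
        )

    # ------------------------------------------------------------- state dict
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=np.float64).reshape(v.data.shape)
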