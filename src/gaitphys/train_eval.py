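"""Objective assembly, training loop, metrics and the robustness harness.

The total objective is

    L = L_c + L_r + L_u + sum_i lambda_i(e, y_f) L_p^(i) + eta ||theta||^2

with cross-entropy classification, mean-squared asymmetry regression,
heteroscedastic Gaussian negative log-likelihood, the four biomechanical
constraint losses weighted by the curriculum schedule, and decoupled L2
regularization.  Constraint terms are normalized per sample/time-step and by
natural physical scales (body weight for forces, (m g)^2 for energy
residuals) so the printed base weights act on O(1) quantities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from . import biomech, segment, synthetic
from .autodiff import AdamW, Tensor, clip_grad_norm, cosine_lr
from .constraints import (
    ConstraintConfig,
    dynamic_loss,
    energy_loss,
    kinematic_loss,
    symmetry_loss,
)
from .model import GaitFatigueNet, ModelConfig
from .schedule import CurriculumConfig, curriculum_alpha, fatigue_beta


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 200
    batch_size: int = 64
    grad_clip: float = 1.0
    seed: int = 0
    val_fraction: float = 0.25  # fraction of subjects held out
    target_val_accuracy: float | None = None  # early stop once reached
    desk: bool = False

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "TrainConfig":
        """Desk-scale profile: 30 epochs, batch 16, higher lr for the tiny model."""
        return cls(lr=3e-3, epochs=30, batch_size=16, seed=seed, desk=True)


@dataclass
class Dataset:
    """Model-ready normalized-cycle arrays."""

    x: np.ndarray  # (n, 101, N, C) raw sensor values
    grf: np.ndarray  # (n, 101, 2) (AP, vertical) N
    y_f: np.ndarray  # (n,) fatigue level 0..4
    y_a: np.ndarray  # (n, 6) asymmetry targets (fractional s-indices)
    subject: np.ndarray  # (n,) subject ids
    mass: np.ndarray  # (n,) kg
    duration: np.ndarray  # (n,) s
    theta_true: np.ndarray | None = None  # (n, 101, 6) generator ground truth

    def __len__(self):
        return self.x.shape[0]


@dataclass
class NormStats:
    mean: np.ndarray  # (N, C)
    sd: np.ndarray  # (N, C)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def asymmetry_targets(theta: np.ndarray) -> np.ndarray:
    """Fractional symmetry indices of per-joint ROM and peak flexion (6 values).

    Ordered (hip, knee, ankle) x (ROM, peak flexion); each value is
    |x_L - x_R| / (0.5 (x_L + x_R)) as a fraction (percent / 100).
    """
    rom_l = theta[..., :3].max(axis=-2) - theta[..., :3].min(axis=-2)
    rom_r = theta[..., 3:].max(axis=-2) - theta[..., 3:].min(axis=-2)
    pk_l = theta[..., :3].max(axis=-2)
    pk_r = theta[..., 3:].max(axis=-2)

    def _s(a, b):
        denom = np.abs(0.5 * (a + b))
        ok = denom > 1e-9
        return np.divide(np.abs(a - b), denom, out=np.zeros_like(denom), where=ok)

    s_rom = _s(rom_l, rom_r)
    s_pk = _s(pk_l, pk_r)
    return np.stack([s_rom[..., 0], s_pk[..., 0], s_rom[..., 1],
                     s_pk[..., 1], s_rom[..., 2], s_pk[..., 2]], axis=-1)


def build_dataset(recordings: list[synthetic.Recording]) -> Dataset:
    """Segment recordings into quality-controlled left-foot cycles."""
    xs, grfs, yfs, yas, subs, masses, durs, thetas = [], [], [], [], [], [], [], []
    for ridx, rec in enumerate(recordings):
        cycles = segment.segment_recording(
            rec.time, rec.sensors, rec.grf_left[:, 1], rec.rate,
            grf_full=rec.grf_left, joint_angles=rec.theta, side="left",
        )
        kept, _ = segment.quality_filter(cycles, rec.profile.mass)
        for c in kept:
            xs.append(c.channels)
            grfs.append(c.grf)
            yfs.append(rec.fatigue_level)
            yas.append(asymmetry_targets(c.joint_angles))
            subs.append(rec.profile.seed)
            masses.append(rec.profile.mass)
            durs.append(c.duration)
            thetas.append(c.joint_angles)
    return Dataset(
        x=np.stack(xs), grf=np.stack(grfs), y_f=np.array(yfs), y_a=np.stack(yas),
        subject=np.array(subs), mass=np.array(masses), duration=np.array(durs),
        theta_true=np.stack(thetas),
    )


def fit_norm_stats(x: np.ndarray) -> NormStats:
    mean = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    sd = np.where(sd < 1e-8, 1.0, sd)
    return NormStats(mean=mean, sd=sd)


def subject_split(dataset: Dataset, val_fraction: float, seed: int):
    """Subject-disjoint train/validation index split."""
    subjects = np.unique(dataset.subject)
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_val = max(1, int(round(val_fraction * len(subjects))))
    val_subj = set(subjects[:n_val].tolist())
    val_idx = np.flatnonzero(np.isin(dataset.subject, list(val_subj)))
    train_idx = np.flatnonzero(~np.isin(dataset.subject, list(val_subj)))
    return train_idx, val_idx


# ------------------------------------------------------------------ objective
@dataclass
class LossBreakdown:
    l_c: float
    l_r: float
    l_u: float
    l_p: tuple[float, float, float, float]
    l2: float
    weights: tuple[float, float, float, float]
    total: float

    def as_dict(self) -> dict[str, float]:
        d = {"l_c": self.l_c, "l_r": self.l_r, "l_u": self.l_u, "l2": self.l2,
             "total": self.total}
        for name, v, w in zip(("kin", "dyn", "sym", "eng"), self.l_p, self.weights):
            d[f"l_{name}"] = v
            d[f"lambda_{name}"] = w
        return d


def total_loss(
    out: dict[str, Tensor],
    y_f: np.ndarray,
    y_a: np.ndarray,
    grf: np.ndarray,
    mass: float,
    duration: float,
    lambdas: np.ndarray,
    eta: float,
    model: GaitFatigueNet,
    ccfg: ConstraintConfig,
    anthro: biomech.AnthropometricModel,
) -> tuple[Tensor, LossBreakdown]:
    """Assemble Eq.-19-style total objective for one batch.

    ``grf`` in Newtons (B, T, 2); ``mass`` and ``duration`` are batch-level
    scalars (the synthetic cohorts are homogeneous enough within a batch that
    the mean is used).  Returns (differentiable total, float breakdown).
    """
    b, t_len = out["class_probs"].shape[0], out["theta"].shape[-2]
    dt = duration / (t_len - 1)
    probs = out["class_probs"]
    eps = 1e-12
    picked = probs[np.arange(b), y_f]
    l_c = -(((picked + eps).log()).mean())
    l_r = ((out["asym"] - Tensor(y_a)) ** 2).mean()
    logvar = out["logvar"]
    err2 = (out["asym"] - Tensor(y_a)) ** 2
    l_u = ((logvar + err2 / logvar.exp()) * 0.5 + 0.5 * np.log(2 * np.pi)).mean()

    bw = mass * biomech.GRAVITY
    theta = out["theta"]
    l_kin = kinematic_loss(theta, ccfg) * (1.0 / (b * t_len))

    st = biomech.biomech_state(theta, dt, anthro)
    f_pred_n = out["f_g"][..., :2] * bw  # head works in body-weight units
    f_meas = grf
    # rotational term: GRF moment about the COM vs whole-body I * alpha
    # (sagittal, about the COM; standing-posture inertia constant)
    com = st.p_c
    tau_e = (com[..., 0] * (-1.0)) * f_pred_n[..., 1] + com[..., 1] * f_pred_n[..., 0]
    i_body = float(np.sum(anthro.inertia_array)) + float(
        anthro.mass_array @ (anthro.mass_array * 0 + 0.2) ** 2
    )
    phi_body = (
        biomech.segment_angles(theta) * Tensor(anthro.mass_array / anthro.total_mass)
    ).sum(axis=-1)
    _, alpha_body = biomech.finite_diff(
        phi_body.reshape(*phi_body.shape, 1), dt, axis=-2
    )
    l_dyn = dynamic_loss(
        f_pred_n, f_meas, st.a_c * 1.0, mass,
        tau_e, i_body, alpha_body[..., 0], ccfg,
    ) * (1.0 / (b * t_len * bw**2))

    l_sym = Tensor(0.0)
    xl, xr = theta[..., 0:3], theta[..., 3:6]
    for lvl in np.unique(y_f):
        idx = np.flatnonzero(y_f == lvl)
        l_sym = l_sym + symmetry_loss(xl[idx], xr[idx], int(lvl), ccfg)
    l_sym = l_sym * (1.0 / (b * t_len))

    e_chain = st.energy
    l_eng_raw = energy_loss(e_chain, f_pred_n, dt, model.params["dissipation_c"])
    e_aux_fit = ((out["e_aux"] - e_chain.detach() * (1.0 / bw)) ** 2).mean()
    l_eng = l_eng_raw * (1.0 / (b * bw**2)) + e_aux_fit * 0.1

    l2 = Tensor(0.0)
    for p in model.weight_parameters():
        l2 = l2 + (p**2).sum()
    l2 = l2 * eta

    total = l_c + l_r + l_u
    for lam, term in zip(lambdas, (l_kin, l_dyn, l_sym, l_eng)):
        total = total + term * float(lam)
    total = total + l2
    bd = LossBreakdown(
        l_c=l_c.item(), l_r=l_r.item(), l_u=l_u.item(),
        l_p=(l_kin.item(), l_dyn.item(), l_sym.item(), l_eng.item()),
        l2=l2.item(), weights=tuple(float(w) for w in lambdas), total=total.item(),
    )
    return total, bd


# ------------------------------------------------------------------- metrics
def evaluate(y_true, y_pred, y_reg_true=None, y_reg_pred=None) -> dict[str, float]:
    """Classification and (optional) regression metrics, standard definitions."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    present = np.unique(y_true)
    all_labels = np.unique(np.concatenate([y_true, y_pred]))
    if len(present) < len(all_labels):
        warnings.warn("empty target class excluded from macro-F1", stacklevel=2)
    out = {
        "accuracy": float(skm.accuracy_score(y_true, y_pred)),
        "macro_f1": float(skm.f1_score(y_true, y_pred, labels=present, average="macro",
                                       zero_division=0)),
        "kappa": float(skm.cohen_kappa_score(y_true, y_pred)),
    }
    if y_reg_true is not None:
        y_reg_true, y_reg_pred = np.asarray(y_reg_true), np.asarray(y_reg_pred)
        out["mae"] = float(skm.mean_absolute_error(y_reg_true, y_reg_pred))
        out["rmse"] = float(np.sqrt(skm.mean_squared_error(y_reg_true, y_reg_pred)))
        out["r2"] = float(skm.r2_score(y_reg_true.ravel(), y_reg_pred.ravel()))
    return out


# ------------------------------------------------------------------ training
@dataclass
class TrainResult:
    model: GaitFatigueNet
    norm: NormStats
    history: list[dict] = field(default_factory=list)
    val_metrics: dict = field(default_factory=dict)
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None


def _validate(model, x, y_f, y_a) -> dict[str, float]:
    preds, regs = [], []
    for i in range(0, x.shape[0], 64):
        out = model.forward(x[i : i + 64])
        preds.append(np.argmax(out["class_probs"].data, axis=-1))
        regs.append(out["asym"].data)
        out["class_probs"].free_graph()
    return evaluate(y_f, np.concatenate(preds), y_a, np.concatenate(regs))


def train(
    dataset: Dataset,
    model: GaitFatigueNet,
    tcfg: TrainConfig,
    ccfg_curr: CurriculumConfig | None = None,
    ccfg_constraints: ConstraintConfig | None = None,
    norm: NormStats | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainResult:
    """Train with AdamW, cosine annealing, gradient clipping and the
    constraint curriculum; logs every loss component per epoch.

    The default training-time constraint config widens the symmetry
    denominator guard to 0.05 rad: near-zero bilateral sums otherwise produce
    unbounded ratios from randomly initialized trajectories and destabilize
    early optimization.  Evaluation-time constraint semantics are unchanged.
    """
    ccfg_curr = ccfg_curr or CurriculumConfig()
    ccfg_constraints = ccfg_constraints or ConstraintConfig(sym_eps=0.05)
    rng = np.random.default_rng(tcfg.seed)
    if split is None:
        split = subject_split(dataset, tcfg.val_fraction, tcfg.seed)
    train_idx, val_idx = split
    if norm is None:
        norm = fit_norm_stats(dataset.x[train_idx])
    xn = norm.apply(dataset.x).astype(dataset.x.dtype)
    anthro = biomech.anthropometrics(1.724, float(dataset.mass.mean()))
    opt = AdamW(model.parameters(), lr=tcfg.lr, weight_decay=0.0)
    history = []
    for epoch in range(tcfg.epochs):
        opt.lr = cosine_lr(tcfg.lr, epoch, tcfg.epochs)
        alpha = curriculum_alpha(epoch, ccfg_curr)
        order = rng.permutation(train_idx)
        ep_bd: list[LossBreakdown] = []
        for i in range(0, len(order), tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            out = model.forward(xn[idx], rng=rng, dropout_on=True)
            beta = fatigue_beta(float(dataset.y_f[idx].mean()), ccfg_curr)
            lambdas = np.asarray(ccfg_curr.base_weights) * alpha * beta
            loss, bd = total_loss(
                out, dataset.y_f[idx], dataset.y_a[idx], dataset.grf[idx],
                float(dataset.mass[idx].mean()), float(dataset.duration[idx].mean()),
                lambdas, tcfg.weight_decay, model, ccfg_constraints, anthro,
            )
            if not np.isfinite(bd.total) or bd.total > 1e6:
                raise RuntimeError(f"divergence at epoch {epoch}: total={bd.total}")
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), tcfg.grad_clip)
            opt.step()
            ep_bd.append(bd)
        val = _validate(model, xn[val_idx], dataset.y_f[val_idx], dataset.y_a[val_idx])
        mean_bd = {
            k: float(np.mean([b.as_dict()[k] for b in ep_bd]))
            for k in ep_bd[0].as_dict()
        }
        mean_bd.update({f"val_{k}": v for k, v in val.items()})
        mean_bd["epoch"] = epoch
        mean_bd["alpha"] = alpha
        history.append(mean_bd)
        if (
            tcfg.target_val_accuracy is not None
            and val["accuracy"] >= tcfg.target_val_accuracy
        ):
            break
    return TrainResult(
        model=model, norm=norm, history=history, val_metrics=history[-1],
        train_idx=train_idx, val_idx=val_idx,
    )


# ---------------------------------------------------------------- checkpoint
def save_checkpoint(path, result: TrainResult, cfg: ModelConfig, opt: AdamW | None = None):
    """Single-file npz archive: weights + config + normalization statistics."""
    arrays = {f"param/{k}": v for k, v in result.model.state_arrays().items()}
    arrays["norm/mean"] = result.norm.mean
    arrays["norm/sd"] = result.norm.sd
    meta = {"model_config": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in cfg.__dict__.items()},
            "bsp_version": 1}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[GaitFatigueNet, NormStats, dict]:
    z = np.load(path)
    meta = json.loads(bytes(z["meta_json"]).decode())
    mc = meta["model_config"]
    for k in ("dilations", "mlp_widths"):
        mc[k] = tuple(mc[k])
    cfg = ModelConfig(**mc)
    model = GaitFatigueNet(cfg, seed=0)
    model.load_state_arrays({k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")})
    norm = NormStats(mean=z["norm/mean"], sd=z["norm/sd"])
    return model, norm, meta


# ---------------------------------------------------------------- robustness
def add_noise_at_snr(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise per channel calibrated to the requested SNR
    against each channel's empirical signal power (near-constant channels
    are left untouched)."""
    power = x.var(axis=(0, 1), keepdims=True)
    sd = np.sqrt(power / (10.0 ** (snr_db / 10.0)))
    sd = np.where(power < 1e-10, 0.0, sd)
    return x + rng.normal(0.0, 1.0, x.shape) * sd


DEFAULT_FAILURE_SCENARIOS = {
    "missing_head": ("head",),
    "missing_trunk_pelvis": ("pelvis",),
    "missing_thigh_one_side": ("thigh_l",),
    "missing_shank_foot_one_side": ("shank_l", "foot_l"),
}


def robustness_suite(
    model: GaitFatigueNet,
    norm: NormStats,
    dataset: Dataset,
    idx: np.ndarray,
    snr_levels: tuple[float, ...] = (20.0, 10.0),
    failure_scenarios: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> list[dict]:
    """Re-evaluate under calibrated sensor noise and zero-masked sensor
    failures; returns rows of a degradation table."""
    failure_scenarios = failure_scenarios or DEFAULT_FAILURE_SCENARIOS
    xn = norm.apply(dataset.x[idx]).astype(np.float32)
    y = dataset.y_f[idx]
    rows = []

    def _acc(xin, mask=None):
        preds = []
        for i in range(0, xin.shape[0], 64):
            out = model.forward(xin[i : i + 64], mask=mask)
            preds.append(np.argmax(out["class_probs"].data, axis=-1))
            out["class_probs"].free_graph()
        m = evaluate(y, np.concatenate(preds))
        return m

    base = _acc(xn)
    rows.append({"condition": "baseline", "scenario": "clean", **base, "delta_acc": 0.0})
    rng = np.random.default_rng(seed)
    for snr in snr_levels:
        m = _acc(add_noise_at_snr(xn, snr, rng).astype(xn.dtype))
        rows.append({"condition": "noise", "scenario": f"snr_{snr:g}dB", **m,
                     "delta_acc": m["accuracy"] - base["accuracy"]})
    for name, sensors in failure_scenarios.items():
        mask = np.ones(len(synthetic.SENSOR_NAMES), dtype=bool)
        for s in sensors:
            mask[synthetic.SENSOR_NAMES.index(s)] = False
        xz = xn.copy()
        xz[:, :, ~mask, :] = 0.0
        m = _acc(xz, mask=mask)
        rows.append({"condition": "sensor_failure", "scenario": name, **m,
                     "delta_acc": m["accuracy"] - base["accuracy"]})
    return rows
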