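"""The four differentiable biomechanical constraint losses.

Each loss is non-negative, exactly zero on physically feasible input, and
built from autodiff primitives so that violation gradients reach every
upstream parameter:

* kinematic  — anatomical joint-range hinge plus second-difference smoothness;
* dynamic    — measured-vs-predicted GRF, linear-momentum balance (sum F =
  m a_c) and rotational balance (sum tau_e = I alpha);
* symmetry   — bilateral trajectory agreement after the half-cycle phase
  shift, with fatigue-dependent relaxation of the weights;
* energy     — per-cycle mechanical work balance with a learnable dissipation
  coefficient c, W_d = c * integral(|F_g|) dt (trapezoid rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, maximum
from .biomech import GRAVITY

_DEG = math.pi / 180.0

# (min, max) anatomical range in radians per DOF; knee is a one-sided range so
# the printed |theta| - theta_max hinge is generalized to interval limits.
DEFAULT_JOINT_LIMITS: dict[str, tuple[float, float]] = {
    "hip_flexion": (-35.0 * _DEG, 35.0 * _DEG),
    "hip_abduction": (-15.0 * _DEG, 15.0 * _DEG),  # optional 2-DOF hip; unused by default
    "knee_flexion": (0.0, 80.0 * _DEG),
    "ankle_flexion": (-30.0 * _DEG, 30.0 * _DEG),
}


@dataclass
class ConstraintConfig:
    joint_limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_JOINT_LIMITS)
    )
    smoothness_kappa: float = 0.1
    kappa1: float = 0.5  # linear-momentum term weight
    kappa2: float = 0.3  # rotational term weight
    sym_base_weights: np.ndarray | None = None  # w_k^0; default ones
    sym_beta: float = 0.15  # fatigue decay of symmetry weights
    sym_eps: float = 1e-6  # denominator guard in the symmetry ratio
    dissipation_init: float = 0.05  # c_0

    def limits_for_joints(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-DOF (lo, hi) arrays for the default sagittal 6-DOF ordering."""
        order = ["hip_flexion", "knee_flexion", "ankle_flexion"] * 2
        lo = np.array([self.joint_limits[k][0] for k in order])
        hi = np.array([self.joint_limits[k][1] for k in order])
        return lo, hi


@dataclass
class ConstraintBundle:
    """The four loss values plus the effective weights applied to them."""

    l_kin: Tensor
    l_dyn: Tensor
    l_sym: Tensor
    l_eng: Tensor
    diagnostics: dict[str, float] = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        return {
            "l_kin": self.l_kin.item(),
            "l_dyn": self.l_dyn.item(),
            "l_sym": self.l_sym.item(),
            "l_eng": self.l_eng.item(),
        }


def kinematic_loss(theta, cfg: ConstraintConfig) -> Tensor:
    """Joint-range hinge + kappa-weighted squared second differences.

    ``theta``: (..., T, J) radians.  Limits are interval limits [lo, hi] per
    DOF with a hinge on each side; within-range, linear-in-time trajectories
    score exactly zero.
    """
    theta = as_tensor(theta)
    lo, hi = cfg.limits_for_joints()
    j = theta.shape[-1]
    lo, hi = lo[:j], hi[:j]
    over = maximum(theta - Tensor(hi), 0.0)
    under = maximum(Tensor(lo) - theta, 0.0)
    range_term = (over**2).sum() + (under**2).sum()
    second = theta[..., 2:, :] - theta[..., 1:-1, :] * 2.0 + theta[..., :-2, :]
    return range_term + (second**2).sum() * cfg.smoothness_kappa


def dynamic_loss(
    f_pred,
    f_meas,
    a_c,
    mass: float,
    tau_e,
    inertia,
    alpha_ang,
    cfg: ConstraintConfig,
) -> Tensor:
    """Newton-Euler consistency loss.

    Terms: ||F_g^p - F_g^m||^2 (masked out when ``f_meas`` is None, i.e.
    inference mode) + kappa1 ||sum F - m a_c||^2 + kappa2 ||sum tau_e -
    I alpha||^2.  Net force sums predicted GRF with gravity; ``f_pred`` and
    ``a_c`` must share their trailing vector dimension.
    """
    f_pred, a_c = as_tensor(f_pred), as_tensor(a_c)
    if f_pred.shape != a_c.shape:
        raise ValueError(f"shape mismatch: f_pred {f_pred.shape} vs a_c {a_c.shape}")
    dim = f_pred.shape[-1]
    g_vec = np.zeros(dim)
    g_vec[1] = -GRAVITY  # vertical axis is component 1 throughout the package
    loss = Tensor(0.0)
    if f_meas is not None:
        f_meas = as_tensor(f_meas)
        if f_meas.shape != f_pred.shape:
            raise ValueError(f"shape mismatch: f_meas {f_meas.shape} vs f_pred {f_pred.shape}")
        loss = loss + ((f_pred - f_meas) ** 2).sum()
    net_f = f_pred + Tensor(g_vec * mass)
    loss = loss + ((net_f - a_c * mass) ** 2).sum() * cfg.kappa1
    tau_e, alpha_ang = as_tensor(tau_e), as_tensor(alpha_ang)
    inertia = as_tensor(inertia)
    loss = loss + ((tau_e - inertia * alpha_ang) ** 2).sum() * cfg.kappa2
    return loss


def symmetry_loss(x_left, x_right, y_f: int, cfg: ConstraintConfig, grid_shift: int = 50) -> Tensor:
    """Bilateral antiphase-symmetry loss on the 101-point cycle grid.

    The right-limb series is cyclically shifted by ``grid_shift`` samples
    (half a cycle on the 101-point grid) and the squared normalized difference
    is accumulated per feature with weights w_k0 * exp(-beta * y_f).  Samples
    where |x_L + x_R_shifted| < eps are excluded via the guard mask.
    """
    xl, xr = as_tensor(x_left), as_tensor(x_right)
    if xl.shape != xr.shape:
        raise ValueError("left/right series must share a shape")
    xr_s = xr.roll(grid_shift, axis=-2)
    denom = xl + xr_s
    guard = np.abs(denom.data) >= cfg.sym_eps
    safe = denom + Tensor(np.where(guard, 0.0, 1.0))
    ratio = (xl - xr_s) / safe * Tensor(guard.astype(float))
    k = xl.shape[-1]
    w0 = np.ones(k) if cfg.sym_base_weights is None else np.asarray(cfg.sym_base_weights, float)
    w = w0 * math.exp(-cfg.sym_beta * y_f)
    return ((ratio**2) * Tensor(w)).sum()


def trapezoid_impulse(f_norm, dt: float) -> Tensor:
    """Trapezoid-rule integral of a (..., T) series along time."""
    f = as_tensor(f_norm)
    return (f[..., 1:] + f[..., :-1]).sum(axis=-1) * (0.5 * dt)


def energy_loss(energy, f_g, dt: float, c: Tensor) -> Tensor:
    """Per-cycle work balance |E(t_f) + W_d - E(t_i)|^2 with W_d = c * impulse.

    ``energy``: (..., T) per-cycle mechanical energy; ``f_g``: (..., T, V)
    ground reaction force whose magnitude is integrated by the trapezoid rule;
    ``c`` is the learnable dissipation scalar and receives gradients.
    """
    e = as_tensor(energy)
    if e.shape[-1] < 2:
        raise ValueError("cycle shorter than 2 samples")
    f = as_tensor(f_g)
    mag = ((f**2).sum(axis=-1) + 1e-12) ** 0.5
    w_d = trapezoid_impulse(mag, dt) * c
    resid = e[..., -1] + w_d - e[..., 0]
    return (resid**2).sum()


def constraint_bundle(
    theta,
    cfg: ConstraintConfig,
    *,
    f_pred=None,
    f_meas=None,
    a_c=None,
    mass: float | None = None,
    tau_e=None,
    inertia=1.0,
    alpha_ang=None,
    x_left=None,
    x_right=None,
    y_f: int = 0,
    energy=None,
    f_g=None,
    dt: float = 0.01,
    c: Tensor | None = None,
) -> ConstraintBundle:
    """Evaluate all four losses; omitted inputs yield zero for that term."""
    zero = Tensor(0.0)
    l_kin = kinematic_loss(theta, cfg) if theta is not None else zero
    if f_pred is not None and a_c is not None:
        te = tau_e if tau_e is not None else np.zeros(np.shape(f_pred.data if isinstance(f_pred, Tensor) else f_pred)[:-1])
        aa = alpha_ang if alpha_ang is not None else np.zeros_like(np.asarray(te, float) if not isinstance(te, Tensor) else te.data)
        l_dyn = dynamic_loss(f_pred, f_meas, a_c, mass, te, inertia, aa, cfg)
    else:
        l_dyn = zero
    l_sym = symmetry_loss(x_left, x_right, y_f, cfg) if x_left is not None else zero
    if energy is not None and f_g is not None:
        cc = c if c is not None else Tensor(cfg.dissipation_init)
        l_eng = energy_loss(energy, f_g, dt, cc)
    else:
        l_eng = zero
    theta_arr = theta.data if isinstance(theta, Tensor) else np.asarray(theta)
    lo, hi = cfg.limits_for_joints()
    viol = np.maximum(theta_arr - hi[: theta_arr.shape[-1]], 0) + np.maximum(
        lo[: theta_arr.shape[-1]] - theta_arr, 0
    )
    diag = {
        "kin_max_violation": float(viol.max()) if viol.size else 0.0,
        "kin_violating_fraction": float((viol > 0).mean()) if viol.size else 0.0,
    }
    return ConstraintBundle(l_kin, l_dyn, l_sym, l_eng, diag)
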