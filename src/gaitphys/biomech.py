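"""Differentiable seven-segment sagittal-plane rigid-body model.

Segments: pelvis-trunk assembly plus bilateral thigh, shank and foot.  Joint
angles ``theta`` are ordered (hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R),
in radians, with 1 sagittal DOF per joint:

* hip: thigh rotation from vertical-down, flexion (forward) positive;
* knee: flexion positive (shank absolute angle = hip angle - knee angle);
* ankle: dorsiflexion positive (foot points forward-horizontal at neutral).

The plane is x forward, y up; rotations are counter-clockwise about the
mediolateral z axis.  All operations are built from autodiff primitives so
constraint gradients flow through the chain theta -> p_s -> p_c -> a_c.

Anthropometrics come from a standard proportion table (Winter body-segment
parameters) shipped as a versioned CSV resource; the pelvis-trunk segment
absorbs the residual mass so segment masses always sum to total body mass.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, stack

log = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2

JOINTS = ("hip_l", "knee_l", "ankle_l", "hip_r", "knee_r", "ankle_r")
SEGMENTS = ("pelvis_trunk", "thigh_l", "shank_l", "foot_l", "thigh_r", "shank_r", "foot_r")


@lru_cache(maxsize=1)
def _bsp_table() -> dict[str, dict[str, float]]:
    text = resources.files("gaitphys.data").joinpath("winter_bsp.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    table = {}
    for row in csv.DictReader(rows):
        table[row["segment"]] = {k: float(v) for k, v in row.items() if k != "segment"}
    return table


@dataclass(frozen=True)
class AnthropometricModel:
    """Segment lengths, masses, inertias and COM offsets for one participant."""

    height: float
    total_mass: float
    segment_lengths: dict[str, float] = field(repr=False)
    segment_masses: dict[str, float] = field(repr=False)
    segment_inertias: dict[str, float] = field(repr=False)
    com_offsets: dict[str, float] = field(repr=False)

    @property
    def mass_array(self) -> np.ndarray:
        return np.array([self.segment_masses[s] for s in SEGMENTS])

    @property
    def inertia_array(self) -> np.ndarray:
        return np.array([self.segment_inertias[s] for s in SEGMENTS])

    @property
    def leg_length(self) -> float:
        return self.segment_lengths["thigh_l"] + self.segment_lengths["shank_l"]


def anthropometrics(height: float, mass: float) -> AnthropometricModel:
    """Estimate segment parameters from stature and body mass.

    Lengths/COM offsets scale with height, masses with body mass, inertias as
    m_s * (gyration_frac * L_s)^2.  The pelvis-trunk segment takes the mass
    residual so that sum(m_s) == mass exactly.
    """
    if not (1.4 <= height <= 2.1):
        raise ValueError(f"height {height} m outside plausible range [1.4, 2.1]")
    if not (40.0 <= mass <= 120.0):
        raise ValueError(f"mass {mass} kg outside plausible range [40, 120]")
    tab = _bsp_table()
    lengths, masses, coms, gyr = {}, {}, {}, {}
    for seg in SEGMENTS:
        base = "pelvis_trunk" if seg == "pelvis_trunk" else seg.rsplit("_", 1)[0]
        lengths[seg] = tab[base]["length_frac"] * height
        coms[seg] = tab[base]["com_frac"]
        gyr[seg] = tab[base]["gyration_frac"]
        if seg != "pelvis_trunk":
            masses[seg] = tab[base]["mass_frac"] * mass
    masses["pelvis_trunk"] = mass - sum(masses.values())
    inertias = {s: masses[s] * (gyr[s] * lengths[s]) ** 2 for s in SEGMENTS}
    return AnthropometricModel(
        height=height,
        total_mass=mass,
        segment_lengths=lengths,
        segment_masses=masses,
        segment_inertias=inertias,
        com_offsets=coms,
    )


# ---------------------------------------------------------------------- FK
def _unit_limb(a: Tensor) -> Tensor:
    """Direction of a limb segment hanging at angle ``a`` from vertical-down."""
    return stack([a.sin(), -(a.cos())], axis=-1)


def _unit_foot(a: Tensor) -> Tensor:
    """Foot long-axis direction; points forward-horizontal at a = 0."""
    return stack([a.cos(), a.sin()], axis=-1)


def _side_angles(theta: Tensor, side: str) -> tuple[Tensor, Tensor, Tensor]:
    off = 0 if side == "l" else 3
    hip = theta[..., off]
    knee = theta[..., off + 1]
    ankle = theta[..., off + 2]
    a_thigh = hip
    a_shank = hip - knee
    a_foot = a_shank + ankle
    return a_thigh, a_shank, a_foot


def forward_kinematics(theta, model: AnthropometricModel, root=None) -> dict[str, Tensor]:
    """Segment joint points and COM positions from joint angles (Eq.-7 role).

    ``theta``: (..., T, 6) radians; ``root``: optional pelvis trajectory
    (..., T, 2), defaults to the origin.  Returns a dict of (..., T, 2)
    tensors: joints hip/knee_{l,r}/ankle_{l,r}/toe_{l,r}/trunk_top and COMs
    com_<segment>.
    """
    theta = as_tensor(theta)
    if root is None:
        root = Tensor(np.zeros(theta.shape[:-1] + (2,)))
    else:
        root = as_tensor(root)
    L = model.segment_lengths
    cf = model.com_offsets
    out: dict[str, Tensor] = {"hip": root}
    up = Tensor(np.array([0.0, 1.0]))
    out["trunk_top"] = root + up * L["pelvis_trunk"]
    out["com_pelvis_trunk"] = root + up * (cf["pelvis_trunk"] * L["pelvis_trunk"])
    for side in ("l", "r"):
        a1, a2, a3 = _side_angles(theta, side)
        u1, u2, u3 = _unit_limb(a1), _unit_limb(a2), _unit_foot(a3)
        knee = root + u1 * L[f"thigh_{side}"]
        ankle = knee + u2 * L[f"shank_{side}"]
        toe = ankle + u3 * L[f"foot_{side}"]
        out[f"knee_{side}"] = knee
        out[f"ankle_{side}"] = ankle
        out[f"toe_{side}"] = toe
        out[f"com_thigh_{side}"] = root + u1 * (cf[f"thigh_{side}"] * L[f"thigh_{side}"])
        out[f"com_shank_{side}"] = knee + u2 * (cf[f"shank_{side}"] * L[f"shank_{side}"])
        out[f"com_foot_{side}"] = ankle + u3 * (cf[f"foot_{side}"] * L[f"foot_{side}"])
    return out


def segment_com_stack(fk: dict[str, Tensor]) -> Tensor:
    """Stack per-segment COM positions in SEGMENTS order -> (..., T, S, 2)."""
    return stack([fk[f"com_{s}"] for s in SEGMENTS], axis=-2)


# ------------------------------------------------------------- derivatives
def _tax(x: Tensor, axis: int, sl: slice) -> Tensor:
    idx = [slice(None)] * x.ndim
    idx[axis] = sl
    return x[tuple(idx)]


def finite_diff(series, dt: float, axis: int = -2) -> tuple[Tensor, Tensor]:
    """First/second time derivatives: central interior, one-sided boundaries.

    Exact for polynomials of degree <= 2; a fixed-coefficient linear operator,
    hence transparent to autodiff.
    """
    x = as_tensor(series)
    t_len = x.shape[axis]
    if t_len < 3:
        raise ValueError("finite_diff requires at least 3 samples")
    inner1 = (_tax(x, axis, slice(2, None)) - _tax(x, axis, slice(None, -2))) * (1.0 / (2 * dt))
    first = concatenate(
        [
            (_tax(x, axis, slice(1, 2)) - _tax(x, axis, slice(0, 1))) * (1.0 / dt),
            inner1,
            (_tax(x, axis, slice(-1, None)) - _tax(x, axis, slice(-2, -1))) * (1.0 / dt),
        ],
        axis=axis,
    )
    inner2 = (
        _tax(x, axis, slice(2, None))
        - _tax(x, axis, slice(1, -1)) * 2.0
        + _tax(x, axis, slice(None, -2))
    ) * (1.0 / dt**2)
    second = concatenate(
        [_tax(inner2, axis, slice(0, 1)), inner2, _tax(inner2, axis, slice(-1, None))],
        axis=axis,
    )
    return first, second


def com_chain(seg_coms, model: AnthropometricModel, dt: float) -> tuple[Tensor, Tensor, Tensor]:
    """Whole-body COM position (Eq.-11 role) and its derivatives (Eq.-12 role).

    ``seg_coms``: (..., T, S, 2) segment COM positions in SEGMENTS order.
    """
    coms = as_tensor(seg_coms)
    m = model.mass_array
    w = Tensor((m / m.sum()).reshape(-1, 1))
    p_c = (coms * w).sum(axis=-2)
    v_c, _ = finite_diff(p_c, dt, axis=-2)
    _, a_c = finite_diff(p_c, dt, axis=-2)
    return p_c, v_c, a_c


# ------------------------------------------------------- exact kinematics
def segment_kinematics(theta, theta_d, theta_dd, model: AnthropometricModel):
    """Analytic per-segment COM acceleration and angular state.

    Differentiates the trigonometric chain in closed form (no grid error), for
    use by inverse dynamics.  Pelvis root assumed stationary.  Returns dict
    per segment name: {com, acc, ang, angvel, angacc}.
    """
    theta, theta_d, theta_dd = as_tensor(theta), as_tensor(theta_d), as_tensor(theta_dd)
    L = model.segment_lengths
    cf = model.com_offsets
    zeros2 = Tensor(np.zeros(theta.shape[:-1] + (2,)))
    zeros1 = Tensor(np.zeros(theta.shape[:-1]))
    out = {
        "pelvis_trunk": {
            "com": zeros2 + Tensor(np.array([0.0, cf["pelvis_trunk"] * L["pelvis_trunk"]])),
            "acc": zeros2,
            "ang": zeros1,
            "angvel": zeros1,
            "angacc": zeros1,
        }
    }
    for side in ("l", "r"):
        a1, a2, a3 = _side_angles(theta, side)
        d1, d2, d3 = _side_angles(theta_d, side)
        dd1, dd2, dd3 = _side_angles(theta_dd, side)
        # u(a) = (sin, -cos): u' = (cos, sin); u'' = -u.  Foot base differs but
        # obeys the same derivative algebra.
        def _pva(a, d, dd, unit, dunit):
            pos = unit(a)
            acc = dunit(a) * stack([dd, dd], axis=-1) - pos * stack([d * d, d * d], axis=-1)
            return pos, acc

        u1, au1 = _pva(a1, d1, dd1, _unit_limb, lambda a: stack([a.cos(), a.sin()], axis=-1))
        u2, au2 = _pva(a2, d2, dd2, _unit_limb, lambda a: stack([a.cos(), a.sin()], axis=-1))
        u3, au3 = _pva(a3, d3, dd3, _unit_foot, lambda a: stack([-(a.sin()), a.cos()], axis=-1))
        lt, ls, lf = L[f"thigh_{side}"], L[f"shank_{side}"], L[f"foot_{side}"]
        ct, cs, cff = cf[f"thigh_{side}"], cf[f"shank_{side}"], cf[f"foot_{side}"]
        out[f"thigh_{side}"] = {
            "com": u1 * (ct * lt),
            "acc": au1 * (ct * lt),
            "ang": a1,
            "angvel": d1,
            "angacc": dd1,
        }
        out[f"shank_{side}"] = {
            "com": u1 * lt + u2 * (cs * ls),
            "acc": au1 * lt + au2 * (cs * ls),
            "ang": a2,
            "angvel": d2,
            "angacc": dd2,
        }
        out[f"foot_{side}"] = {
            "com": u1 * lt + u2 * ls + u3 * (cff * lf),
            "acc": au1 * lt + au2 * ls + au3 * (cff * lf),
            "ang": a3,
            "angvel": d3,
            "angacc": dd3,
        }
        out[f"_ankle_{side}"] = {"pos": u1 * lt + u2 * ls}
        out[f"_knee_{side}"] = {"pos": u1 * lt}
        out[f"_cop_{side}"] = {"pos": u1 * lt + u2 * ls + u3 * (0.5 * lf)}
    return out


def _cross2(r: Tensor, f: Tensor) -> Tensor:
    return r[..., 0] * f[..., 1] - r[..., 1] * f[..., 0]


def inverse_dynamics(
    theta,
    theta_d,
    theta_dd,
    model: AnthropometricModel,
    grf_left=None,
    grf_right=None,
    cop_frac: float = 0.5,
) -> Tensor:
    """Planar recursive Newton-Euler joint torques (Eq.-8 role).

    External ground reaction forces (..., T, 2) = (anterior-posterior,
    vertical) act at a fixed centre-of-pressure fraction of foot length.
    Missing forces fall back to gravity-only dynamics with a logged warning.
    Returns torques (..., T, 6) in JOINTS order, counter-clockwise positive,
    torque exerted by the proximal on the distal segment.
    """
    theta = as_tensor(theta)
    if grf_left is None and grf_right is None:
        log.warning("inverse_dynamics called without GRF; gravity-only dynamics")
    kin = segment_kinematics(theta, theta_d, theta_dd, model)
    g_vec = Tensor(np.array([0.0, -GRAVITY]))
    zero2 = Tensor(np.zeros(theta.shape[:-1] + (2,)))
    taus = {}
    for side, grf in (("l", grf_left), ("r", grf_right)):
        f_ext = as_tensor(grf) if grf is not None else zero2
        m_f = model.segment_masses[f"foot_{side}"]
        m_s = model.segment_masses[f"shank_{side}"]
        m_t = model.segment_masses[f"thigh_{side}"]
        i_f = model.segment_inertias[f"foot_{side}"]
        i_s = model.segment_inertias[f"shank_{side}"]
        i_t = model.segment_inertias[f"thigh_{side}"]
        foot, shank, thigh = kin[f"foot_{side}"], kin[f"shank_{side}"], kin[f"thigh_{side}"]
        p_ankle = kin[f"_ankle_{side}"]["pos"]
        p_knee = kin[f"_knee_{side}"]["pos"]
        p_hip = zero2
        # COP at cop_frac of foot length from the ankle along the foot axis
        p_cop = p_ankle + (kin[f"_cop_{side}"]["pos"] - p_ankle) * (cop_frac / 0.5)
        # foot: proximal joint = ankle, external GRF at COP
        f_a = foot["acc"] * m_f - g_vec * m_f - f_ext
        tau_a = (
            foot["angacc"] * i_f
            - _cross2(p_ankle - foot["com"], f_a)
            - _cross2(p_cop - foot["com"], f_ext)
        )
        # shank: distal reaction from foot
        f_k = shank["acc"] * m_s - g_vec * m_s + f_a
        tau_k = (
            shank["angacc"] * i_s
            + tau_a
            - _cross2(p_knee - shank["com"], f_k)
            + _cross2(p_ankle - shank["com"], f_a)
        )
        # thigh: distal reaction from shank
        f_h = thigh["acc"] * m_t - g_vec * m_t + f_k
        tau_h = (
            thigh["angacc"] * i_t
            + tau_k
            - _cross2(p_hip - thigh["com"], f_h)
            + _cross2(p_knee - thigh["com"], f_k)
        )
        taus[f"hip_{side}"] = tau_h
        taus[f"knee_{side}"] = tau_k
        taus[f"ankle_{side}"] = tau_a
    return stack([taus[j] for j in JOINTS], axis=-1)


def total_energy(v_c, omega, h_c, model: AnthropometricModel) -> Tensor:
    """Total mechanical energy E(t) = 1/2 m|v_c|^2 + 1/2 sum I_s w_s^2 + m g h_c.

    ``omega``: per-segment angular velocities (..., T, S) in SEGMENTS order.
    """
    v_c, omega, h_c = as_tensor(v_c), as_tensor(omega), as_tensor(h_c)
    m = model.total_mass
    kin_t = (v_c**2).sum(axis=-1) * (0.5 * m)
    kin_r = (omega**2 * Tensor(model.inertia_array)).sum(axis=-1) * 0.5
    pot = h_c * (m * GRAVITY)
    return kin_t + kin_r + pot


def segment_angles(theta) -> Tensor:
    """Absolute segment angles (..., T, S) in SEGMENTS order (pelvis = 0)."""
    theta = as_tensor(theta)
    cols = [Tensor(np.zeros(theta.shape[:-1]))]
    for side in ("l", "r"):
        a1, a2, a3 = _side_angles(theta, side)
        cols.extend([a1, a2, a3])
    order = ["pelvis_trunk", "thigh_l", "shank_l", "foot_l", "thigh_r", "shank_r", "foot_r"]
    mapping = {
        "pelvis_trunk": 0, "thigh_l": 1, "shank_l": 2, "foot_l": 3,
        "thigh_r": 4, "shank_r": 5, "foot_r": 6,
    }
    return stack([cols[mapping[s]] for s in order], axis=-1)


@dataclass
class BiomechState:
    """Per-cycle physical quantities derived from predicted joint angles."""

    theta: Tensor
    theta_d: Tensor
    theta_dd: Tensor
    fk: dict[str, Tensor]
    p_c: Tensor
    v_c: Tensor
    a_c: Tensor
    energy: Tensor


def biomech_state(theta, dt: float, model: AnthropometricModel) -> BiomechState:
    """Run the full differentiable chain theta -> p_s -> p_c -> v_c/a_c -> E."""
    theta = as_tensor(theta)
    theta_d, theta_dd = finite_diff(theta, dt, axis=-2)
    fk = forward_kinematics(theta, model)
    coms = segment_com_stack(fk)
    p_c, v_c, a_c = com_chain(coms, model, dt)
    omega, _ = finite_diff(segment_angles(theta), dt, axis=-2)
    energy = total_energy(v_c, omega, p_c[..., 1], model)
    return BiomechState(theta, theta_d, theta_dd, fk, p_c, v_c, a_c, energy)
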