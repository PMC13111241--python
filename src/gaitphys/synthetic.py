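"""Seeded synthetic gait cohort generator.

Emulates the statistical structure the method assumes without any recorded
dataset: quasi-periodic sagittal joint-angle trajectories built from a
truncated Fourier gait template, a double-bump vertical ground reaction force
scaled to body weight, and fatigue-dependent growth of bilateral asymmetry,
amplitude jitter and cadence drift.  Eight IMU frames (head, pelvis/trunk,
bilateral thigh, shank, foot) are synthesized from forward kinematics:
accelerometers by double differentiation plus gravity in the sensor frame,
gyroscopes from segment angular velocity, magnetometers as a rotated constant
north field.  Everything is deterministic under a fixed seed.

Fatigue levels 0..4 map to five protocol stages from baseline to severe
fatigue; effect sizes are chosen so that the bilateral ROM symmetry index
grows by roughly 2.5% per level per unit asymmetry gain, within the range
reported for fatiguing gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import biomech

RATE_HZ = 100.0
DT = 1.0 / RATE_HZ

SENSOR_NAMES = (
    "head", "pelvis", "thigh_l", "thigh_r", "shank_l", "shank_r", "foot_l", "foot_r"
)
CHANNEL_NAMES = (
    "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "mag_x", "mag_y", "mag_z"
)
CHANNEL_CLASS = ("acc",) * 3 + ("gyro",) * 3 + ("mag",) * 3

DEFAULT_NOISE_SD = {"acc": 0.05, "gyro": 0.01, "mag": 0.005, "grf": 2.0}

# Fourier gait template per joint: (mean, [(amplitude, harmonic, phase), ...]).
# Amplitudes sit inside the anatomical ranges with margin at baseline.
_TEMPLATE = {
    "hip": (0.08, [(0.40, 1, 0.0), (0.04, 2, -1.2)]),
    "knee": (0.50, [(0.35, 1, -2.2), (0.12, 2, 0.8)]),
    "ankle": (0.05, [(0.18, 1, 2.0), (0.10, 2, 0.5)]),
}
# per-level bilateral offset growth (rad per level per unit asymmetry_gain)
_OFFSET_UNIT = {"hip": 0.045, "knee": 0.055, "ankle": 0.028}
# right-limb amplitude deficit per level per unit asymmetry_gain
_AMP_DEFICIT_UNIT = 0.025
STANCE_FRACTION = 0.62


@dataclass(frozen=True)
class SubjectProfile:
    height: float  # m
    mass: float  # kg
    base_cadence: float = 108.0  # steps/min
    asymmetry_gain: float = 1.0  # dimensionless, per fatigue level
    variability_gain: float = 0.02  # amplitude jitter sd per fatigue level
    seed: int = 0

    def __post_init__(self):
        if not (1.4 <= self.height <= 2.1):
            raise ValueError("height outside [1.4, 2.1] m")
        if not (40.0 <= self.mass <= 120.0):
            raise ValueError("mass outside [40, 120] kg")
        if self.asymmetry_gain < 0 or self.variability_gain < 0:
            raise ValueError("gains must be non-negative")


@dataclass(frozen=True)
class SyntheticCycleSpec:
    fatigue_level: int
    stride_duration: float  # s
    joint_amplitude_scale: tuple[float, ...] = (1.0,) * 6
    left_right_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rad per joint
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self):
        if self.fatigue_level not in range(5):
            raise ValueError("fatigue_level must be in {0..4}")
        if not (0.4 <= self.stride_duration <= 1.2):
            raise ValueError("stride_duration outside [0.4, 1.2] s")


def default_cycle_spec(fatigue_level: int, profile: SubjectProfile) -> SyntheticCycleSpec:
    """Study-condition spec for one cycle: offsets and cadence drift by level."""
    # cadence slows ~1.5% per level; stride duration = 2 steps
    stride = 120.0 / (profile.base_cadence * (1.0 - 0.015 * fatigue_level))
    off = tuple(
        _OFFSET_UNIT[j] * profile.asymmetry_gain * fatigue_level
        for j in ("hip", "knee", "ankle")
    )
    # keep a margin inside the [0.4, 1.2] s quality window so +-1-sample
    # detection jitter cannot push a default cycle over the duration rule
    return SyntheticCycleSpec(
        fatigue_level=fatigue_level,
        stride_duration=float(np.clip(stride, 0.42, 1.18)),
        left_right_offset=off,
    )


def _joint_series(phase: np.ndarray, joint: str, amp_scale: float) -> np.ndarray:
    mean, harmonics = _TEMPLATE[joint]
    out = np.full_like(phase, mean)
    for amp, h, ph in harmonics:
        out += amp_scale * amp * np.cos(2 * np.pi * h * phase + ph)
    return out


def generate_joint_trajectories(
    spec: SyntheticCycleSpec,
    profile: SubjectProfile,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One gait cycle of joint angles (T, 6) in biomech.JOINTS order.

    The right limb follows the left template shifted by half a cycle, plus the
    spec's bilateral offsets and a fatigue-scaled amplitude deficit.
    Cycle-to-cycle amplitude jitter grows with fatigue level.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    t_len = int(round(spec.stride_duration * RATE_HZ))
    phase = np.arange(t_len) / t_len
    lvl = spec.fatigue_level
    jitter_sd = profile.variability_gain * lvl
    amp_r_deficit = 1.0 - _AMP_DEFICIT_UNIT * profile.asymmetry_gain * lvl
    theta = np.empty((t_len, 6))
    for j, joint in enumerate(("hip", "knee", "ankle")):
        jit_l = 1.0 + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        jit_r = 1.0 + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        scale_l = spec.joint_amplitude_scale[j] * jit_l
        scale_r = spec.joint_amplitude_scale[3 + j] * jit_r * amp_r_deficit
        theta[:, j] = _joint_series(phase, joint, scale_l)
        theta[:, 3 + j] = _joint_series((phase + 0.5) % 1.0, joint, scale_r) + spec.left_right_offset[j]
    return theta


def _grf_cycle(phase: np.ndarray, body_weight: float, phase_offset: float = 0.0) -> np.ndarray:
    """Double-bump vertical + braking/propulsive AP force, (T, 2) = (AP, vertical)."""
    ph = (phase + phase_offset) % 1.0
    stance = ph < STANCE_FRACTION
    s = np.where(stance, ph / STANCE_FRACTION, 0.0)
    # double-bump loading curve; peaks ~1.1 BW at ~22%/78% stance, dip ~0.85 BW
    shape = 1.25 * (np.sin(np.pi * s) + 0.32 * np.sin(3 * np.pi * s))
    vert = np.where(stance, body_weight * shape, 0.0)
    ap = np.where(stance, -0.18 * body_weight * np.sin(2 * np.pi * s), 0.0)
    return np.stack([ap, vert], axis=-1)


def _sensor_sites(theta: np.ndarray, model: biomech.AnthropometricModel, root: np.ndarray):
    """World position (T, 2) and orientation angle (T,) per sensor site."""
    fk = biomech.forward_kinematics(theta, model, root=root)
    ang = biomech.segment_angles(theta).data  # (T, 7) in SEGMENTS order
    pos = {
        "head": fk["trunk_top"].data,
        "pelvis": fk["hip"].data,
        "thigh_l": fk["com_thigh_l"].data,
        "thigh_r": fk["com_thigh_r"].data,
        "shank_l": fk["com_shank_l"].data,
        "shank_r": fk["com_shank_r"].data,
        "foot_l": fk["com_foot_l"].data,
        "foot_r": fk["com_foot_r"].data,
    }
    seg_for_sensor = {
        "head": 0, "pelvis": 0, "thigh_l": 1, "shank_l": 2, "foot_l": 3,
        "thigh_r": 4, "shank_r": 5, "foot_r": 6,
    }
    angles = {name: ang[..., seg_for_sensor[name]] for name in SENSOR_NAMES}
    return pos, angles


def synthesize_sensors(
    theta: np.ndarray,
    profile: SubjectProfile,
    noise_sd: dict | None = None,
    seed: int = 0,
    root: np.ndarray | None = None,
    snr_db: float | None = None,
) -> np.ndarray:
    """IMU channels (T, 8, 9) from a joint-angle series at 100 Hz.

    Accelerometer = R^T (p_ddot - g) (gravity included, units m/s^2);
    gyroscope = segment angular rate about the mediolateral axis (z channel);
    magnetometer = unit north field rotated into the sensor frame.  Additive
    Gaussian noise: per channel-class standard deviations, or calibrated
    per-channel to ``snr_db`` against that channel's AC signal power
    (near-constant channels receive no noise).
    """
    model = biomech.anthropometrics(profile.height, profile.mass)
    t_len = theta.shape[0]
    if root is None:
        root = np.zeros((t_len, 2))
    pos, angles = _sensor_sites(theta, model, root)
    data = np.zeros((t_len, len(SENSOR_NAMES), len(CHANNEL_NAMES)))
    for si, name in enumerate(SENSOR_NAMES):
        p = pos[name]
        phi = angles[name]
        if t_len >= 3:
            vel = np.gradient(p, DT, axis=0)
            acc = np.gradient(vel, DT, axis=0)
            om = np.gradient(phi, DT)
        else:
            acc = np.zeros_like(p)
            om = np.zeros_like(phi)
        spec_force = acc - np.array([0.0, -biomech.GRAVITY])  # a - g
        c, s = np.cos(phi), np.sin(phi)
        data[:, si, 0] = c * spec_force[:, 0] + s * spec_force[:, 1]
        data[:, si, 1] = -s * spec_force[:, 0] + c * spec_force[:, 1]
        data[:, si, 5] = om  # gyro_z: sagittal angular rate
        data[:, si, 6] = c  # north field in sensor frame
        data[:, si, 7] = -s
    rng = np.random.default_rng(seed)
    if snr_db is not None:
        power = data.var(axis=0)  # AC power per (sensor, channel)
        sd = np.sqrt(power / (10.0 ** (snr_db / 10.0)))
        sd[power < 1e-12] = 0.0
        data = data + rng.normal(0.0, 1.0, data.shape) * sd
    else:
        sds = noise_sd if noise_sd is not None else DEFAULT_NOISE_SD
        for ci, cls in enumerate(CHANNEL_CLASS):
            data[:, :, ci] += rng.normal(0.0, sds.get(cls, 0.0), (t_len, len(SENSOR_NAMES)))
    return data


@dataclass
class Recording:
    """A continuous multi-cycle synthetic recording for one subject/level."""

    profile: SubjectProfile
    fatigue_level: int
    time: np.ndarray  # (T,)
    sensors: np.ndarray  # (T, 8, 9)
    theta: np.ndarray  # (T, 6) ground-truth joint angles
    grf_left: np.ndarray  # (T, 2) (AP, vertical) N
    grf_right: np.ndarray  # (T, 2)
    cycle_starts_left: np.ndarray  # sample index of each left IC (ground truth)
    cycle_starts_right: np.ndarray

    @property
    def rate(self) -> float:
        return RATE_HZ


def generate_recording(
    profile: SubjectProfile,
    fatigue_level: int,
    n_cycles: int,
    seed: int | None = None,
    noise_sd: dict | None = None,
    snr_db: float | None = None,
) -> Recording:
    """Concatenate ``n_cycles`` strides into one continuous labeled recording."""
    seed = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    spec = default_cycle_spec(fatigue_level, profile)
    thetas, grfs_l, grfs_r, starts = [], [], [], []
    idx = 0
    bw = profile.mass * biomech.GRAVITY
    for _ in range(n_cycles):
        theta_c = generate_joint_trajectories(spec, profile, rng=rng)
        t_len = theta_c.shape[0]
        phase = np.arange(t_len) / t_len
        thetas.append(theta_c)
        grfs_l.append(_grf_cycle(phase, bw, 0.0))
        grfs_r.append(_grf_cycle(phase, bw, 0.5))
        starts.append(idx)
        idx += t_len
    theta = np.concatenate(thetas, axis=0)
    t_total = theta.shape[0]
    # vertical pelvis excursion: two oscillations per stride, ~1.5 cm amplitude
    phase_all = np.concatenate(
        [np.arange(th.shape[0]) / th.shape[0] for th in thetas]
    )
    root = np.zeros((t_total, 2))
    root[:, 1] = -0.015 * np.cos(4 * np.pi * phase_all)
    sensors = synthesize_sensors(
        theta, profile, noise_sd=noise_sd, seed=seed + 1, root=root, snr_db=snr_db
    )
    grf_l = np.concatenate(grfs_l, axis=0)
    grf_r = np.concatenate(grfs_r, axis=0)
    grf_noise = (noise_sd or DEFAULT_NOISE_SD).get("grf", 0.0) if snr_db is None else 0.0
    if grf_noise > 0:
        g_rng = np.random.default_rng(seed + 2)
        clean_l, clean_r = grf_l[:, 1].copy(), grf_r[:, 1].copy()
        grf_l = grf_l + g_rng.normal(0, grf_noise, grf_l.shape)
        grf_r = grf_r + g_rng.normal(0, grf_noise, grf_r.shape)
        # swing phase stays identically zero so contact edges remain unique
        grf_l[:, 1] = np.where(clean_l > 0, np.maximum(grf_l[:, 1], 0.0), 0.0)
        grf_r[:, 1] = np.where(clean_r > 0, np.maximum(grf_r[:, 1], 0.0), 0.0)
    starts_l = np.asarray(starts)
    # right IC lags left by half a stride
    starts_r = starts_l + np.array([th.shape[0] // 2 for th in thetas])
    return Recording(
        profile=profile,
        fatigue_level=fatigue_level,
        time=np.arange(t_total) * DT,
        sensors=sensors,
        theta=theta,
        grf_left=grf_l,
        grf_right=grf_r,
        cycle_starts_left=starts_l,
        cycle_starts_right=starts_r[starts_r < t_total],
    )


def sample_profiles(n_subjects: int, seed: int, **gains) -> list[SubjectProfile]:
    """Draw subject anthropometrics from the cohort statistics (172.4 +/- 8.1 cm,
    68.2 +/- 11.3 kg), clipped to plausible ranges."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        h = float(np.clip(rng.normal(1.724, 0.081), 1.5, 2.0))
        m = float(np.clip(rng.normal(68.2, 11.3), 45.0, 110.0))
        cad = float(np.clip(rng.normal(108.0, 6.0), 90.0, 130.0))
        profiles.append(
            SubjectProfile(
                height=h, mass=m, base_cadence=cad,
                seed=int(rng.integers(0, 2**31 - 1)),
                **gains,
            )
        )
    return profiles


def easy_cohort(seed: int, n_subjects: int = 5, cycles_per_level: int = 12) -> list[Recording]:
    """The 'easy' five-class cohort for smoke-learning experiments: strong,
    consistent fatigue effect sizes (doubled asymmetry growth, 3% amplitude
    jitter per level) with the default sensor noise."""
    return make_cohort(
        n_subjects, cycles_per_level, seed,
        asymmetry_gain=2.0, variability_gain=0.03,
    )


def make_cohort(
    n_subjects: int,
    cycles_per_level: int,
    seed: int,
    levels: tuple[int, ...] = (0, 1, 2, 3, 4),
    noise_sd: dict | None = None,
    asymmetry_gain: float = 1.0,
    variability_gain: float = 0.02,
) -> list[Recording]:
    """One recording per (subject, fatigue level); the cohort study conditions."""
    profiles = sample_profiles(
        n_subjects, seed, asymmetry_gain=asymmetry_gain, variability_gain=variability_gain
    )
    recs = []
    for p in profiles:
        for lvl in levels:
            recs.append(
                generate_recording(
                    p, lvl, cycles_per_level, seed=p.seed + 1000 * lvl, noise_sd=noise_sd
                )
            )
    return recs
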