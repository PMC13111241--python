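"""Per-cycle biomechanical descriptors: a fixed manifest of 127 features.

The descriptor count is a conformance property: the manifest below is frozen
and always emitted in full, with unavailable descriptors flagged missing
(NaN + mask) rather than dropped.  Domains:

* spatiotemporal (11): bilateral stride/stance/swing/contact/aerial timing
  plus cadence;
* kinematic (33): per-joint peak flexion/extension, range of motion, IC/TC
  angles for bilateral hip/knee/ankle, plus trunk lateral/anterior
  inclination and axial rotation ranges;
* kinetic (10): per-side peak vertical force, loading rate,
  braking/propulsive impulses, vertical COM displacement;
* symmetry (48): ratio r = x_L/x_R, difference d = x_L - x_R and the
  normalized index s = |x_L - x_R| / (0.5 (x_L + x_R)) * 100% for 16
  designated bilateral base features;
* frequency (25): dominant frequency, normalized spectral entropy and
  low/medium/high band power fractions for 5 designated channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import integrate, signal

from .biomech import GRAVITY
from .segment import NormalizedCycle
from .synthetic import SENSOR_NAMES

N_FEATURES = 127
DOMAINS = ("spatiotemporal", "kinematic", "kinetic", "symmetry", "frequency")

_JOINTS3 = ("hip", "knee", "ankle")
_SIDES = ("l", "r")
_KINEMATIC_STATS = ("peak_flexion", "peak_extension", "rom", "ic_angle", "tc_angle")
_KINETIC_STATS = (
    "peak_vertical_force",
    "loading_rate",
    "braking_impulse",
    "propulsive_impulse",
    "vertical_com_displacement",
)
# bilateral base features entering the symmetry domain (16 of them)
_SYMMETRY_BASES = (
    "stride_duration",
    "stance_fraction",
    "swing_fraction",
    "contact_duration",
    "aerial_duration",
    "hip_rom",
    "knee_rom",
    "ankle_rom",
    "hip_peak_flexion",
    "knee_peak_flexion",
    "ankle_peak_flexion",
    "peak_vertical_force",
    "loading_rate",
    "braking_impulse",
    "propulsive_impulse",
    "vertical_com_displacement",
)
# (sensor, channel-index, tag) for the frequency domain (5 channels)
_SPECTRAL_CHANNELS = (
    ("pelvis", 1, "pelvis_acc_vert"),
    ("foot_l", 1, "foot_l_acc_vert"),
    ("shank_l", 5, "shank_l_gyro_sag"),
    ("shank_r", 5, "shank_r_gyro_sag"),
    ("head", 1, "head_acc_vert"),
)
_SPECTRAL_STATS = ("dominant_freq", "spectral_entropy", "band_low", "band_mid", "band_high")


def build_manifest() -> list[tuple[str, str, str]]:
    """(name, domain, unit) triples in frozen output order."""
    man: list[tuple[str, str, str]] = []
    for side in _SIDES:
        man += [
            (f"stride_duration_{side}", "spatiotemporal", "s"),
            (f"stance_fraction_{side}", "spatiotemporal", "fraction"),
            (f"swing_fraction_{side}", "spatiotemporal", "fraction"),
            (f"contact_duration_{side}", "spatiotemporal", "s"),
            (f"aerial_duration_{side}", "spatiotemporal", "s"),
        ]
    man.append(("cadence", "spatiotemporal", "steps/min"))
    for side in _SIDES:
        for joint in _JOINTS3:
            for stat in _KINEMATIC_STATS:
                man.append((f"{joint}_{stat}_{side}", "kinematic", "rad"))
    man += [
        ("trunk_lateral_inclination_range", "kinematic", "rad"),
        ("trunk_anterior_inclination_range", "kinematic", "rad"),
        ("trunk_axial_rotation_range", "kinematic", "rad"),
    ]
    for side in _SIDES:
        units = {"peak_vertical_force": "N", "loading_rate": "N/s",
                 "braking_impulse": "N*s", "propulsive_impulse": "N*s",
                 "vertical_com_displacement": "m"}
        for stat in _KINETIC_STATS:
            man.append((f"{stat}_{side}", "kinetic", units[stat]))
    for base in _SYMMETRY_BASES:
        man += [
            (f"sym_ratio_{base}", "symmetry", "dimensionless"),
            (f"sym_diff_{base}", "symmetry", "base units"),
            (f"sym_index_{base}", "symmetry", "percent"),
        ]
    for _, _, tag in _SPECTRAL_CHANNELS:
        units = {"dominant_freq": "Hz", "spectral_entropy": "dimensionless",
                 "band_low": "fraction", "band_mid": "fraction", "band_high": "fraction"}
        for stat in _SPECTRAL_STATS:
            man.append((f"{tag}_{stat}", "frequency", units[stat]))
    assert len(man) == N_FEATURES
    assert len({m[0] for m in man}) == N_FEATURES
    return man


MANIFEST = build_manifest()
MANIFEST_NAMES = tuple(m[0] for m in MANIFEST)


@dataclass
class FeatureSet:
    values: np.ndarray  # (127,) in manifest order; NaN where missing
    missing: np.ndarray  # (127,) bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MANIFEST_NAMES, self.values))


@dataclass
class SymmetryIndices:
    ratio: float
    difference: float
    index_percent: float
    missing: bool = False


def symmetry_indices(x_left: float, x_right: float) -> SymmetryIndices:
    """Bilateral ratio, difference and normalized symmetry index.

    s = |x_L - x_R| / (0.5 (x_L + x_R)) * 100%, bounded by 200% for
    non-negative inputs.  Zero denominators flag the value missing rather
    than producing infinities.
    """
    d = x_left - x_right
    if x_right == 0 or (x_left + x_right) == 0:
        return SymmetryIndices(math.nan, d, math.nan, missing=True)
    r = x_left / x_right
    s = abs(d) / (0.5 * (x_left + x_right)) * 100.0
    return SymmetryIndices(r, d, s)


def spectral_descriptors(x: np.ndarray, rate: float) -> dict[str, float]:
    """FFT descriptors of a detrended cycle-grid channel.

    Dominant frequency over the 0-20 Hz analysis band (DC excluded);
    spectral entropy -sum p log p over the normalized band power spectrum,
    reported normalized by log(n_bins) to [0, 1]; band power fractions for
    0-3, 3-8 and 8-20 Hz sum to 1.  All-zero input flags everything missing.
    """
    x = np.asarray(x, dtype=float)
    x = signal.detrend(x)
    if np.allclose(x, 0.0):
        return {k: math.nan for k in _SPECTRAL_STATS}
    n = x.shape[0]
    freqs = sp_fft.rfftfreq(n, d=1.0 / rate)
    power = np.abs(sp_fft.rfft(x)) ** 2
    band = (freqs > 0) & (freqs <= 20.0)
    p = power[band]
    f = freqs[band]
    total = p.sum()
    if total <= 0:
        return {k: math.nan for k in _SPECTRAL_STATS}
    pn = p / total
    entropy = -np.sum(pn * np.log(pn + 1e-300)) / math.log(pn.size)
    return {
        "dominant_freq": float(f[np.argmax(p)]),
        "spectral_entropy": float(entropy),
        "band_low": float(pn[f <= 3.0].sum()),
        "band_mid": float(pn[(f > 3.0) & (f <= 8.0)].sum()),
        "band_high": float(pn[f > 8.0].sum()),
    }


def loading_rate(grf_vertical: np.ndarray, dt: float, window_s: float = 0.02) -> float:
    """Max mean slope of the vertical force over a sliding 20 ms window
    during weight acceptance (first half of the cycle)."""
    f = np.asarray(grf_vertical, float)
    w = max(1, int(round(window_s / dt)))
    half = f[: max(w + 1, f.shape[0] // 2)]
    slopes = (half[w:] - half[:-w]) / (w * dt)
    return float(np.max(slopes)) if slopes.size else math.nan


def _impulses(grf_ap: np.ndarray, dt: float) -> tuple[float, float]:
    """Braking (negative-AP) and propulsive (positive-AP) impulses, N*s."""
    f = np.asarray(grf_ap, float)
    braking = integrate.trapezoid(np.minimum(f, 0.0), dx=dt)
    propulsive = integrate.trapezoid(np.maximum(f, 0.0), dx=dt)
    return float(braking), float(propulsive)


def vertical_com_displacement(trunk_acc_vert: np.ndarray, dt: float) -> float:
    """Peak-to-peak vertical COM excursion from trunk acceleration.

    Gravity-free vertical acceleration is double-integrated with mean removal
    at each stage (a high-pass drift correction appropriate for one cycle).
    """
    a = np.asarray(trunk_acc_vert, float) - np.mean(trunk_acc_vert)
    v = integrate.cumulative_trapezoid(a, dx=dt, initial=0.0)
    v -= v.mean()
    p = integrate.cumulative_trapezoid(v, dx=dt, initial=0.0)
    return float(np.ptp(p))


def _trunk_angles(cycle: NormalizedCycle) -> dict[str, float]:
    """Trunk inclination/rotation ranges from the pelvis-sensor channels.

    Anterior inclination from the sagittal accelerometer tilt
    atan2(acc_x, acc_y); lateral from atan2(acc_z, acc_y); axial rotation
    range by integrating the vertical-axis gyro channel.
    """
    si = SENSOR_NAMES.index("pelvis")
    acc = cycle.channels[:, si, 0:3]
    gyr = cycle.channels[:, si, 3:6]
    dt = cycle.duration / (cycle.channels.shape[0] - 1)
    anterior = np.arctan2(acc[:, 0], np.maximum(acc[:, 1], 1e-6))
    lateral = np.arctan2(acc[:, 2], np.maximum(acc[:, 1], 1e-6))
    yaw = integrate.cumulative_trapezoid(gyr[:, 1], dx=dt, initial=0.0)
    return {
        "trunk_lateral_inclination_range": float(np.ptp(lateral)),
        "trunk_anterior_inclination_range": float(np.ptp(anterior)),
        "trunk_axial_rotation_range": float(np.ptp(yaw)),
    }


def _side_values(cycle: NormalizedCycle, side: str, mass: float) -> dict[str, float]:
    """All per-side scalar descriptors for one normalized cycle."""
    vals: dict[str, float] = {}
    dt = cycle.duration / (cycle.channels.shape[0] - 1)
    grf_v = None if cycle.grf is None else cycle.grf[:, -1]
    vals["stride_duration"] = cycle.duration
    if grf_v is not None:
        stance = float(np.mean(grf_v > 20.0))
        vals["stance_fraction"] = stance
        vals["swing_fraction"] = 1.0 - stance
        vals["contact_duration"] = stance * cycle.duration
        vals["aerial_duration"] = max(0.0, (1.0 - 2 * stance)) * cycle.duration
        vals["peak_vertical_force"] = float(np.max(grf_v))
        vals["loading_rate"] = loading_rate(grf_v, dt)
        if cycle.grf.shape[1] >= 2:
            b, p = _impulses(cycle.grf[:, 0], dt)
            vals["braking_impulse"] = b
            vals["propulsive_impulse"] = p
        else:
            vals["braking_impulse"] = math.nan
            vals["propulsive_impulse"] = math.nan
    else:
        for k in ("stance_fraction", "swing_fraction", "contact_duration",
                  "aerial_duration", "peak_vertical_force", "loading_rate",
                  "braking_impulse", "propulsive_impulse"):
            vals[k] = math.nan
    si = SENSOR_NAMES.index("pelvis")
    vals["vertical_com_displacement"] = vertical_com_displacement(
        cycle.channels[:, si, 1] - GRAVITY, dt
    )
    if cycle.joint_angles is not None:
        off = 0 if side == "l" else 3
        for j, joint in enumerate(_JOINTS3):
            th = cycle.joint_angles[:, off + j]
            stance_end = (
                int(np.argmax(grf_v[1:] < 30.0)) + 1 if grf_v is not None and (grf_v[1:] < 30.0).any()
                else th.shape[0] - 1
            )
            vals[f"{joint}_peak_flexion"] = float(np.max(th))
            vals[f"{joint}_peak_extension"] = float(np.min(th))
            vals[f"{joint}_rom"] = float(np.ptp(th))
            vals[f"{joint}_ic_angle"] = float(th[0])
            vals[f"{joint}_tc_angle"] = float(th[stance_end])
    else:
        for joint in _JOINTS3:
            for stat in _KINEMATIC_STATS:
                vals[f"{joint}_{stat}"] = math.nan
    return vals


def extract_features(
    left: NormalizedCycle, right: NormalizedCycle, mass: float
) -> FeatureSet:
    """Compute the full 127-descriptor set for a left/right cycle pair.

    Sensor-derived descriptors come from each side's own cycle; symmetry
    descriptors pair the per-side base features.  Missing inputs (e.g. no
    GRF) propagate NaN + mask, never a shortened vector.
    """
    lv = _side_values(left, "l", mass)
    rv = _side_values(right, "r", mass)
    rate = (left.channels.shape[0] - 1) / left.duration
    out: dict[str, float] = {}
    for side, v in (("l", lv), ("r", rv)):
        out[f"stride_duration_{side}"] = v["stride_duration"]
        out[f"stance_fraction_{side}"] = v["stance_fraction"]
        out[f"swing_fraction_{side}"] = v["swing_fraction"]
        out[f"contact_duration_{side}"] = v["contact_duration"]
        out[f"aerial_duration_{side}"] = v["aerial_duration"]
    out["cadence"] = 120.0 / (0.5 * (lv["stride_duration"] + rv["stride_duration"]))
    for side, v in (("l", lv), ("r", rv)):
        for joint in _JOINTS3:
            for stat in _KINEMATIC_STATS:
                out[f"{joint}_{stat}_{side}"] = v[f"{joint}_{stat}"]
    out.update(_trunk_angles(left))
    for side, v in (("l", lv), ("r", rv)):
        for stat in _KINETIC_STATS:
            out[f"{stat}_{side}"] = v[stat]
    for base in _SYMMETRY_BASES:
        xl, xr = lv[base], rv[base]
        if math.isnan(xl) or math.isnan(xr):
            si = SymmetryIndices(math.nan, math.nan, math.nan, missing=True)
        else:
            si = symmetry_indices(xl, xr)
        out[f"sym_ratio_{base}"] = si.ratio
        out[f"sym_diff_{base}"] = si.difference
        out[f"sym_index_{base}"] = si.index_percent
    for sensor, ci, tag in _SPECTRAL_CHANNELS:
        sidx = SENSOR_NAMES.index(sensor)
        desc = spectral_descriptors(left.channels[:, sidx, ci], rate)
        for stat in _SPECTRAL_STATS:
            out[f"{tag}_{stat}"] = desc[stat]
    values = np.array([out[name] for name in MANIFEST_NAMES])
    return FeatureSet(values=values, missing=np.isnan(values))
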