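"""Gait-cycle segmentation, temporal normalization and quality control.

Initial contact (IC) is detected on the vertical ground reaction force as an
upward crossing of 20 N; terminal contact (TC) as a downward crossing of
30 N, with hysteresis (after an IC only a TC is accepted and vice versa) and
a 50 ms debounce.  When force is unavailable a kinematic backup detects IC
from shank sagittal angular-velocity zero crossings (the negative-to-positive
crossing that follows the mid-swing positive peak).  A cycle runs from one IC
to the next IC of the same foot, half-open in samples; each kept cycle is
cubic-spline resampled onto the canonical 101-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .biomech import GRAVITY

GRID_POINTS = 101
MIN_EVENT_SPACING_S = 0.05
DURATION_RANGE_S = (0.4, 1.2)
PEAK_FORCE_MIN_BW = 0.8


@dataclass
class ContactEvents:
    initial_contacts: np.ndarray
    terminal_contacts: np.ndarray
    source: str  # "force" | "kinematic"

    def __post_init__(self):
        ic, tc = np.asarray(self.initial_contacts), np.asarray(self.terminal_contacts)
        if (np.diff(ic) <= 0).any() or (np.diff(tc) <= 0).any():
            raise ValueError("contact indices must be strictly increasing")
        self.initial_contacts, self.terminal_contacts = ic, tc


@dataclass
class NormalizedCycle:
    """One gait cycle resampled to the canonical 0-100% grid."""

    grid: np.ndarray  # (101,) percent of cycle
    channels: np.ndarray  # (101, N, C)
    grf: np.ndarray | None  # (101, V) or None
    duration: float  # s
    side: str  # "left" | "right"
    subject_id: str = ""
    fatigue_level: int | None = None
    joint_angles: np.ndarray | None = None  # (101, 6) when available


def detect_contacts_force(
    grf_vertical: np.ndarray,
    rate: float = 100.0,
    rise_thresh: float = 20.0,
    fall_thresh: float = 30.0,
) -> ContactEvents:
    """Threshold-crossing contact events on the vertical force channel."""
    f = np.asarray(grf_vertical, dtype=float)
    if (f < -1e-9).any():
        raise ValueError("vertical force must be non-negative")
    min_gap = int(round(MIN_EVENT_SPACING_S * rate))
    ics, tcs = [], []
    expect = "ic" if f[0] < rise_thresh else "tc"
    last_event = -min_gap - 1
    for t in range(1, f.shape[0]):
        if expect == "ic" and f[t - 1] < rise_thresh <= f[t]:
            if t - last_event > min_gap:
                ics.append(t)
                last_event = t
                expect = "tc"
        elif expect == "tc" and f[t - 1] >= fall_thresh > f[t]:
            if t - last_event > min_gap:
                tcs.append(t)
                last_event = t
                expect = "ic"
    return ContactEvents(np.asarray(ics, int), np.asarray(tcs, int), source="force")


def detect_contacts_kinematic(shank_gyro_sagittal: np.ndarray, rate: float = 100.0) -> ContactEvents:
    """Backup IC detection from shank angular velocity.

    Convention (counter-clockwise-positive sagittal rate, x forward / y up):
    the shank swings forward through a mid-swing positive peak, then reverses
    as the leg extends for contact; the first zero crossing after that peak
    marks IC.  The convention is validated against force-based events on
    noiseless synthetic recordings.
    """
    w = np.asarray(shank_gyro_sagittal, dtype=float)
    min_gap = int(round(MIN_EVENT_SPACING_S * rate))
    peak_thresh = 0.3 * np.max(w) if w.size and np.max(w) > 0 else 0.0
    if peak_thresh <= 0:
        return ContactEvents(np.array([], int), np.array([], int), source="kinematic")
    ics = []
    armed = False
    last = -min_gap - 1
    for t in range(1, w.shape[0]):
        if w[t] >= peak_thresh:
            armed = True
        if armed and w[t - 1] > 0 >= w[t] and t - last > min_gap:
            ics.append(t)
            last = t
            armed = False
    return ContactEvents(np.asarray(ics, int), np.array([], int), source="kinematic")


def normalize_cycle(
    time_s: np.ndarray,
    channels: np.ndarray,
    grf: np.ndarray | None = None,
    side: str = "left",
    subject_id: str = "",
    fatigue_level: int | None = None,
    joint_angles: np.ndarray | None = None,
) -> NormalizedCycle:
    """Cubic-spline resample all channels onto 101 uniform points (0-100%)."""
    time_s = np.asarray(time_s, dtype=float)
    if time_s.shape[0] < 4:
        raise ValueError("cycle too short to resample (need >= 4 samples)")
    if (np.diff(time_s) <= 0).any():
        raise ValueError("non-monotonic timestamps")
    u = (time_s - time_s[0]) / (time_s[-1] - time_s[0])
    grid = np.linspace(0.0, 1.0, GRID_POINTS)

    def _resample(arr):
        flat = arr.reshape(arr.shape[0], -1)
        out = interpolate.CubicSpline(u, flat, axis=0)(grid)
        return out.reshape((GRID_POINTS,) + arr.shape[1:])

    return NormalizedCycle(
        grid=grid * 100.0,
        channels=_resample(np.asarray(channels, float)),
        grf=None if grf is None else _resample(np.asarray(grf, float)),
        duration=float(time_s[-1] - time_s[0]),
        side=side,
        subject_id=subject_id,
        fatigue_level=fatigue_level,
        joint_angles=None if joint_angles is None else _resample(np.asarray(joint_angles, float)),
    )


@dataclass
class RejectionLog:
    entries: list[tuple[int, str]] = field(default_factory=list)

    def add(self, idx: int, reason: str):
        self.entries.append((idx, reason))


def quality_filter(
    cycles: list[NormalizedCycle], body_mass: float
) -> tuple[list[NormalizedCycle], RejectionLog]:
    """Keep cycles passing the three printed rules; log which rule fired.

    Rules: duration in [0.4, 1.2] s; peak vertical force >= 80% body weight
    (checked only when force is present); monotonic timestamps (encoded here
    as a non-negative finite duration grid — non-monotonic raw cycles are
    rejected before normalization and logged by the caller).
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    bw = body_mass * GRAVITY
    kept, log = [], RejectionLog()
    for i, c in enumerate(cycles):
        if not (DURATION_RANGE_S[0] <= c.duration <= DURATION_RANGE_S[1]):
            log.add(i, "duration")
            continue
        if c.grf is not None and np.max(c.grf[..., -1]) < PEAK_FORCE_MIN_BW * bw:
            log.add(i, "force")
            continue
        if not np.all(np.isfinite(c.channels)):
            log.add(i, "timestamps")
            continue
        kept.append(c)
    return kept, log


def segment_recording(
    time_s: np.ndarray,
    sensors: np.ndarray,
    grf_vertical: np.ndarray | None,
    rate: float,
    shank_gyro: np.ndarray | None = None,
    **cycle_meta,
) -> list[NormalizedCycle]:
    """Cut one foot's cycles IC_i..IC_{i+1} and normalize each to the grid.

    Force-based events are preferred; the kinematic backup is used when no
    force crossings exist.  First/last partial cycles are discarded
    implicitly (cycles exist only between successive detected ICs).
    """
    if grf_vertical is not None:
        ev = detect_contacts_force(grf_vertical, rate=rate)
        ics = ev.initial_contacts
    else:
        ics = np.array([], int)
    if ics.size == 0 and shank_gyro is not None:
        ics = detect_contacts_kinematic(shank_gyro, rate=rate).initial_contacts
    out = []
    grf_full = cycle_meta.pop("grf_full", None)
    joint_angles = cycle_meta.pop("joint_angles", None)
    for a, b in zip(ics[:-1], ics[1:]):
        sl = slice(a, b + 1)  # include the closing IC sample for resampling
        out.append(
            normalize_cycle(
                time_s[sl],
                sensors[sl],
                grf=None if grf_full is None else grf_full[sl],
                joint_angles=None if joint_angles is None else joint_angles[sl],
                **cycle_meta,
            )
        )
    return out
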