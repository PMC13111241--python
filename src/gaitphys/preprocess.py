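"""Signal conditioning: zero-phase low-pass filtering, complementary-filter
orientation estimation, modified-Z outlier repair, z-score normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "SensorArray",
    "OrientationEstimate",
    "lowpass",
    "estimate_orientation",
    "repair_outliers",
    "zscore",
]


@dataclass
class SensorArray:
    """Multi-sensor time series (T samples, N sensors, C channels) + metadata."""

    data: np.ndarray
    rate: float
    sensor_names: tuple[str, ...]
    channel_names: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        t, n, c = self.data.shape
        if n != len(self.sensor_names) or c != len(self.channel_names):
            raise ValueError("data shape inconsistent with sensor/channel names")


@dataclass
class OrientationEstimate:
    quaternions: np.ndarray  # (T, 4) unit quaternions, scalar first
    filter_alpha: float
    dt: float


def lowpass(x: np.ndarray, rate: float, cutoff: float = 20.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, so effective order 2x)."""
    x = np.asarray(x, dtype=float)
    if rate <= 2 * cutoff:
        raise ValueError(f"rate {rate} Hz must exceed twice the cutoff {cutoff} Hz")
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise ValueError(f"series of length {x.shape[0]} too short for order-{order} filtering")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


# ----------------------------------------------------------- quaternion ops
def _qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _qconj(q: np.ndarray) -> np.ndarray:
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def _rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    qv = np.concatenate([[0.0], v])
    return _qmul(_qmul(q, qv), _qconj(q))[1:]


def _q_from_accel_mag(accel: np.ndarray, mag: np.ndarray, g_ref: np.ndarray, m_ref: np.ndarray):
    """Tilt from the gravity direction, yaw from the horizontal magnetometer
    projection (TRIAD-style attitude from the two reference vectors)."""

    def _frame(g, m):
        d = g / np.linalg.norm(g)
        e1 = np.cross(d, m)
        n1 = np.linalg.norm(e1)
        if n1 < 1e-12:  # magnetic field parallel to gravity: yaw unobservable
            e1 = np.cross(d, np.array([1.0, 0.0, 0.0]))
            n1 = np.linalg.norm(e1)
        e1 /= n1
        e2 = np.cross(e1, d)
        return np.stack([e2, e1, d], axis=1)

    r_body = _frame(-accel, mag)  # gravity points opposite the specific force
    r_ref = _frame(g_ref, m_ref)  # g_ref is already the gravity direction
    rot = r_ref @ r_body.T
    # rotation matrix -> quaternion (scalar first)
    tr = np.trace(rot)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        q = np.array(
            [0.25 * s, (rot[2, 1] - rot[1, 2]) / s, (rot[0, 2] - rot[2, 0]) / s, (rot[1, 0] - rot[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(rot)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + rot[i, i] - rot[j, j] - rot[k, k]) * 2
        q = np.empty(4)
        q[0] = (rot[k, j] - rot[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (rot[j, i] + rot[i, j]) / s
        q[1 + k] = (rot[k, i] + rot[i, k]) / s
    return q / np.linalg.norm(q)


def estimate_orientation(
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray,
    alpha: float = 0.98,
    dt: float = 0.01,
    g_ref: np.ndarray | None = None,
    m_ref: np.ndarray | None = None,
) -> OrientationEstimate:
    """Complementary-filter orientation from gyro/accel/mag at each step.

    The gyro contribution uses the proper quaternion increment
    q (x) [1, omega*dt/2] (the printed additive form is dimensionally
    informal); the accelerometer-magnetometer attitude q_am is blended in with
    weight (1 - alpha) and the estimate renormalized every step.  Zero-norm
    accelerometer samples fall back to a gyro-only update.
    """
    gyro, accel, mag = (np.asarray(a, float) for a in (gyro, accel, mag))
    t_len = gyro.shape[0]
    g_ref = np.array([0.0, 0.0, -9.81]) if g_ref is None else np.asarray(g_ref, float)
    m_ref = np.array([1.0, 0.0, 0.0]) if m_ref is None else np.asarray(m_ref, float)
    q = np.zeros((t_len, 4))
    q_prev = (
        _q_from_accel_mag(accel[0], mag[0], g_ref, m_ref)
        if np.linalg.norm(accel[0]) > 1e-9
        else np.array([1.0, 0.0, 0.0, 0.0])
    )
    for t in range(t_len):
        half = 0.5 * gyro[t] * dt
        q_gyro = _qmul(q_prev, np.concatenate([[1.0], half]))
        if np.linalg.norm(accel[t]) > 1e-9 and alpha < 1.0:
            q_am = _q_from_accel_mag(accel[t], mag[t], g_ref, m_ref)
            if np.dot(q_am, q_gyro) < 0:
                q_am = -q_am
            q_t = alpha * q_gyro + (1.0 - alpha) * q_am
        else:
            q_t = q_gyro
        q_t = q_t / np.linalg.norm(q_t)
        q[t] = q_t
        q_prev = q_t
    return OrientationEstimate(quaternions=q, filter_alpha=alpha, dt=dt)


def repair_outliers(
    x: np.ndarray, z_thresh: float = 3.5, max_gap: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Modified-Z outlier detection with cubic-spline repair of short runs.

    Modified Z = 0.6745 * (x - median) / MAD (Iglewicz-Hoaglin).  Flagged runs
    of length <= ``max_gap`` are replaced by a cubic spline through the
    unflagged neighbours; longer runs stay unrepaired but flagged in the mask.
    Returns (repaired, mask) where mask marks all flagged samples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("repair_outliers expects a 1-D series")
    if x.shape[0] < 10:
        raise ValueError("series too short (need >= 10 samples)")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x.copy(), np.zeros_like(x, dtype=bool)
    z = 0.6745 * (x - med) / mad
    mask = np.abs(z) > z_thresh
    repaired = x.copy()
    if not mask.any():
        return repaired, mask
    good = ~mask
    if good.sum() >= 4:
        spline = interpolate.CubicSpline(np.flatnonzero(good), x[good])
        # repair only runs short enough to be isolated anomalies
        idx = np.flatnonzero(mask)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) <= max_gap:
                repaired[run] = spline(run)
    return repaired, mask


def zscore(x: np.ndarray, ref_mean, ref_sd) -> np.ndarray:
    """(x - ref_mean) / ref_sd with reference statistics from training data."""
    ref_sd = np.asarray(ref_sd, dtype=float)
    if np.any(ref_sd <= 0):
        raise ValueError("ref_sd must be strictly positive")
    return (np.asarray(x, float) - ref_mean) / ref_sd
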