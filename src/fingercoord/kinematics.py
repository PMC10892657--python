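"""MCP joint kinematics from 3D joint-center trajectories.

The flexion angle of a metacarpophalangeal (MCP) joint is the angle between
the vertical +Z0 axis and the proximal phalanx vector P0->P1, obtained from
the clamped arccos of their dot product. Angular velocity and acceleration
follow by numerical differentiation (second-order central differences with
second-order one-sided end stencils). Keystroke cycles are segmented by the
metronome period, since the synthetic protocol is phase-locked to the beat.

All public interfaces use degrees; radians appear only inside trig calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synth import HandTrajectory

__all__ = [
    "JointAngleSeries",
    "DegenerateSegmentError",
    "mcp_angle",
    "segment_angle",
    "differentiate",
    "moving_average",
    "extract_angles",
    "segment_cycles",
    "write_angles",
]

Z0 = np.array([0.0, 0.0, 1.0])


class DegenerateSegmentError(ValueError):
    """A phalanx segment has (near-)zero length; the angle is undefined."""


@dataclass
class JointAngleSeries:
    """Per-frame MCP kinematics for one recording set.

    theta1/omega1/alpha1 are the middle-finger MCP angle and its first two
    time derivatives; beta1 is the ring-finger MCP angle. PIP/DIP angles
    (theta2/theta3) are optional extras unused by the coordination model.
    ``cycle_bounds`` holds half-open [start, end) frame-index pairs.
    """

    time_s: np.ndarray
    theta1_deg: np.ndarray
    omega1_deg_s: np.ndarray
    alpha1_deg_s2: np.ndarray
    beta1_deg: np.ndarray
    theta2_deg: np.ndarray | None = None
    theta3_deg: np.ndarray | None = None
    cycle_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("theta1_deg", "omega1_deg_s", "alpha1_deg_s2", "beta1_deg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time_s")
        prev_end = 0
        for a, b in self.cycle_bounds:
            if not (0 <= a < b <= n) or a < prev_end:
                raise ValueError("cycle_bounds must be ordered, disjoint, in range")
            prev_end = b

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


def mcp_angle(p0, p1, up_axis=Z0):
    """Angle (degrees, in [0, 180]) between ``up_axis`` and the segment p0->p1.

    Accepts single points or (..., 3) stacks. The dot product is clamped to
    [-1, 1] before arccos, so valid segments never produce NaN.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    u = np.asarray(up_axis, dtype=float)
    u = u / np.linalg.norm(u)
    seg = p1 - p0
    norm = np.linalg.norm(seg, axis=-1)
    if np.any(norm <= 1e-6):
        bad = np.nonzero(np.atleast_1d(norm) <= 1e-6)[0]
        raise DegenerateSegmentError(
            f"zero-length phalanx segment at indices {bad.tolist()}"
        )
    cosang = np.clip(np.sum(seg * u, axis=-1) / norm, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if ang.ndim == 0 else ang


def segment_angle(v_from, v_to):
    """Unsigned angle (degrees) between two phalanx vectors (PIP/DIP angles)."""
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na <= 1e-6) or np.any(nb <= 1e-6):
        raise DegenerateSegmentError("zero-length phalanx segment")
    cosang = np.clip(np.sum(a * b, axis=-1) / (na * nb), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if ang.ndim == 0 else ang


def _check_uniform(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    step = dt[0]
    if np.max(np.abs(dt - step)) > 1e-9 * max(step, 1.0):
        raise ValueError("differentiate requires a uniform time step")
    return float(step)


def differentiate(series: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    """d(series)/dt on a uniform grid.

    Central differences at interior points, second-order one-sided stencils
    at the two ends (this is np.gradient with edge_order=2); exact on linear
    and affine signals, O(dt^2) accurate on smooth ones. Applying it twice
    yields the angular acceleration from the angle.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series and time_s must have the same length")
    if y.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = _check_uniform(t)
    return np.gradient(y, dt, edge_order=2)


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 1")
    if window == 1:
        return np.asarray(series, dtype=float).copy()
    half = window // 2
    padded = np.pad(np.asarray(series, dtype=float), half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def extract_angles(
    traj: HandTrajectory,
    smoothing_window: int = 1,
    include_pip_dip: bool = False,
) -> JointAngleSeries:
    """Joint-angle series from a trajectory.

    theta1/beta1 come from the P0->P1 segments of the middle/ring fingers;
    optional PIP/DIP angles from consecutive phalanx vectors. A centered
    moving average (``smoothing_window`` > 1, odd) is applied to the angles
    before differentiation — recommended (window 5) for noisy recordings.
    """
    mid = traj.finger("middle")
    ring = traj.finger("ring")
    theta1 = mcp_angle(mid[:, 0], mid[:, 1])
    beta1 = mcp_angle(ring[:, 0], ring[:, 1])
    theta1 = moving_average(theta1, smoothing_window)
    beta1 = moving_average(beta1, smoothing_window)
    omega1 = differentiate(theta1, traj.time_s)
    alpha1 = differentiate(omega1, traj.time_s)
    theta2 = theta3 = None
    if include_pip_dip:
        v01 = mid[:, 1] - mid[:, 0]
        v12 = mid[:, 2] - mid[:, 1]
        v23 = mid[:, 3] - mid[:, 2]
        theta2 = moving_average(segment_angle(v01, v12), smoothing_window)
        theta3 = moving_average(segment_angle(v12, v23), smoothing_window)
    return JointAngleSeries(
        time_s=traj.time_s.copy(),
        theta1_deg=theta1,
        omega1_deg_s=omega1,
        alpha1_deg_s2=alpha1,
        beta1_deg=beta1,
        theta2_deg=theta2,
        theta3_deg=theta3,
    )


def segment_cycles(
    series: JointAngleSeries, cycle_period_s: float
) -> JointAngleSeries:
    """Segment a metronome-locked series into fixed-length keystroke cycles.

    Windows of ``cycle_period_s`` aligned to t = 0; the partial trailing
    window is discarded. Returns a copy with ``cycle_bounds`` filled in.
    """
    if cycle_period_s <= 0:
        raise ValueError("cycle_period_s must be positive")
    dt = _check_uniform(series.time_s)
    if cycle_period_s < 2 * dt:
        raise ValueError("cycle period shorter than two sample intervals")
    n = series.n_frames
    ratio = cycle_period_s / dt
    bounds: list[tuple[int, int]] = []
    if abs(ratio - round(ratio)) < 1e-6:
        per = int(round(ratio))
        for k in range(n // per):
            bounds.append((k * per, (k + 1) * per))
    else:
        duration = n * dt
        k = 0
        while (k + 1) * cycle_period_s <= duration + 1e-9:
            a = int(np.ceil(k * ratio - 1e-9))
            b = int(np.ceil((k + 1) * ratio - 1e-9))
            bounds.append((a, min(b, n)))
            k += 1
    return replace(series, cycle_bounds=bounds)


def write_angles(path, series: JointAngleSeries) -> None:
    """Angles CSV: time_s,theta1_deg,omega1_deg_s,alpha1_deg_s2,beta1_deg."""
    pd.DataFrame(
        {
            "time_s": series.time_s,
            "theta1_deg": series.theta1_deg,
            "omega1_deg_s": series.omega1_deg_s,
            "alpha1_deg_s2": series.alpha1_deg_s2,
            "beta1_deg": series.beta1_deg,
        }
    ).to_csv(path, index=False, float_format="%.6f")
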