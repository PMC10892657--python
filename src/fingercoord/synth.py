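"""Synthetic coordinated-keystroke data generator.

The study this package models collected middle/ring-finger joint-center
trajectories from 12 professional pianists performing metronome-paced
coordinated keystrokes (one ~0.75 s flexion--extension cycle per beat, sets
of 25 consecutive keystrokes). Those recordings are private, so this module
generates cohorts with the same protocol structure and a *known* injected
coupling between the middle-finger MCP angle (theta1) and the ring-finger MCP
angle (beta1), modulated by subject covariates (finger lengths, years of
training). Because the ground-truth coupling law is known, every downstream
stage — angle extraction, network training, metaheuristic initialization,
evaluation — can be tested quantitatively.

Geometry convention: each finger is a planar three-link chain in the Y0–Z0
plane (x == 0 in noiseless mode). Joint centers P0..P3 are the MCP, PIP, DIP
and fingertip. The MCP angle is measured from the vertical +Z0 axis to the
proximal phalanx vector P0->P1.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectProfile",
    "PopulationParams",
    "CouplingLaw",
    "GeneratorConfig",
    "HandTrajectory",
    "TrajectoryParseError",
    "TrajectorySchemaError",
    "sample_subjects",
    "middle_mcp_profile",
    "true_ring_angle",
    "generate_session",
    "generate_cohort",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]

FINGERS = ("middle", "ring")
JOINTS = ("P0", "P1", "P2", "P3")

#: proximal/middle/distal phalanx lengths as fractions of total finger length
#: (standard anthropometric split; only the proximal segment enters the model).
PHALANX_FRACTIONS = (0.46, 0.31, 0.23)

#: resting offset of the ring-finger MCP center from the middle-finger MCP
#: center, in mm (one white-key width along -Y0).
RING_P0_OFFSET_MM = np.array([0.0, -23.5, 0.0])


class TrajectoryParseError(ValueError):
    """Raised for malformed trajectory files (bad values, bad time column)."""


class TrajectorySchemaError(ValueError):
    """Raised when a trajectory file lacks required columns."""


@dataclass(frozen=True)
class SubjectProfile:
    """Covariates of one participant entering the multi-individual model."""

    subject_id: str
    middle_length_mm: float
    ring_length_mm: float
    training_years: float

    def __post_init__(self) -> None:
        for name in ("middle_length_mm", "ring_length_mm"):
            v = getattr(self, name)
            if not 40.0 < v < 130.0:
                raise ValueError(f"{name}={v!r} outside plausible (40, 130) mm")
        if not 0.0 <= self.training_years <= 60.0:
            raise ValueError(
                f"training_years={self.training_years!r} outside [0, 60]"
            )


@dataclass(frozen=True)
class PopulationParams:
    """Cohort-level distributions the subject sampler draws from.

    Defaults match the study population: middle finger 84.4 +/- 4.3 mm,
    ring finger 79.1 +/- 4.5 mm, training years uniform on [5, 15].
    """

    middle_mean_mm: float = 84.4
    middle_sd_mm: float = 4.3
    ring_mean_mm: float = 79.1
    ring_sd_mm: float = 4.5
    training_low_years: float = 5.0
    training_high_years: float = 15.0


@dataclass(frozen=True)
class CouplingLaw:
    """Ground-truth mapping from theta1 history and covariates to beta1.

    beta1(t) = offset + gain(profile) * theta1(t - lag), with

        gain(profile) = gain_base
                      + gain_length_coeff * (ring_length - middle_length)
                      + gain_training_coeff * training_years

    The linear-with-lag default is representable by the 13-unit network, so
    parameter recovery is a meaningful test surface. ``saturating=True``
    applies a mild tanh compression to theta1 for robustness experiments.
    """

    gain_base: float = 0.85
    gain_length_coeff: float = 0.01
    gain_training_coeff: float = 0.005
    lag_s: float = 0.05
    offset_deg: float = 2.0
    saturating: bool = False
    saturation_scale_deg: float = 60.0

    def gain(self, profile: SubjectProfile) -> float:
        return (
            self.gain_base
            + self.gain_length_coeff
            * (profile.ring_length_mm - profile.middle_length_mm)
            + self.gain_training_coeff * profile.training_years
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Protocol parameters for one synthetic recording campaign."""

    n_subjects: int = 12
    sets_per_subject: int = 30
    keystrokes_per_set: int = 25
    cycle_period_s: float = 0.75
    sample_rate_hz: float = 100.0
    rest_angle_deg: float = 10.0
    amplitude_deg: float = 40.0
    pip_ratio: float = 0.5
    dip_ratio: float = 0.3
    angle_noise_sd_deg: float = 2.0
    position_noise_sd_mm: float = 0.5
    coupling: CouplingLaw = field(default_factory=CouplingLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "sets_per_subject", "keystrokes_per_set"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sample_rate_hz * self.cycle_period_s < 20:
            raise ValueError(
                "fewer than 20 frames per keystroke cycle: raise "
                "sample_rate_hz or cycle_period_s"
            )
        if self.angle_noise_sd_deg < 0 or self.position_noise_sd_mm < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.coupling.lag_s <= self.cycle_period_s / 4:
            raise ValueError("coupling lag_s must lie in [0, cycle_period/4]")

    @property
    def frames_per_set(self) -> int:
        return int(
            round(
                self.keystrokes_per_set
                * self.cycle_period_s
                * self.sample_rate_hz
            )
        )


@dataclass
class HandTrajectory:
    """Joint-center positions for both fingers over one recording set.

    ``positions`` has shape (n_frames, 2 fingers, 4 joints, 3 coords) in mm,
    indexed by :data:`FINGERS` and :data:`JOINTS`; coordinates are (x, y, z)
    in the fixed frame of the middle-finger MCP center.
    """

    subject_id: str
    set_index: int
    time_s: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.time_s.shape[0]
        if self.positions.shape != (n, 2, 4, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} frames x 2 fingers x 4 joints x 3 coords"
            )
        if n == 0:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.time_s)) or not np.all(
            np.isfinite(self.positions)
        ):
            raise ValueError("trajectory contains non-finite values")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time_s.shape[0]

    def finger(self, name: str) -> np.ndarray:
        """(n_frames, 4, 3) positions of one finger ('middle' or 'ring')."""
        return self.positions[:, FINGERS.index(name)]


def sample_subjects(
    n: int,
    population: PopulationParams | None = None,
    rng_seed: int = 0,
) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles from the cohort distributions.

    Finger lengths come from normals truncated to the anatomically plausible
    (40, 130) mm range; training years from a uniform distribution.
    Deterministic for a fixed ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = population or PopulationParams()
    rng = np.random.default_rng(rng_seed)

    def trunc_normal(mean: float, sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.full(size, mean)
        a, b = (40.0 - mean) / sd, (130.0 - mean) / sd
        return stats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, size=size, random_state=rng
        )

    middle = trunc_normal(pop.middle_mean_mm, pop.middle_sd_mm, n)
    ring = trunc_normal(pop.ring_mean_mm, pop.ring_sd_mm, n)
    years = rng.uniform(pop.training_low_years, pop.training_high_years, n)
    return [
        SubjectProfile(
            subject_id=f"data{i + 1:02d}",
            middle_length_mm=float(middle[i]),
            ring_length_mm=float(ring[i]),
            training_years=float(years[i]),
        )
        for i in range(n)
    ]


def middle_mcp_profile(
    t_in_cycle,
    cycle_period_s: float,
    amplitude_deg: float,
    rest_angle_deg: float = 10.0,
):
    """Noiseless middle-finger MCP angle at phase ``t_in_cycle`` of one cycle.

    A C2-smooth single-peak flexion pulse:
    ``rest + amplitude * sin^2(pi * t / T)`` — starts and ends the cycle at
    the rest angle with one peak of ``amplitude_deg`` at mid-cycle.
    """
    t = np.asarray(t_in_cycle, dtype=float)
    if np.any(t < 0) or np.any(t >= cycle_period_s):
        raise ValueError("t_in_cycle must lie in [0, cycle_period_s)")
    if not 0.0 < amplitude_deg < 90.0:
        raise ValueError("amplitude_deg must lie in (0, 90)")
    out = rest_angle_deg + amplitude_deg * np.sin(np.pi * t / cycle_period_s) ** 2
    return float(out) if np.isscalar(t_in_cycle) else out


def true_ring_angle(
    theta_deg: np.ndarray,
    time_s: np.ndarray,
    profile: SubjectProfile,
    law: CouplingLaw,
) -> np.ndarray:
    """Ground-truth ring-finger MCP angle beta1 from the middle-finger theta1.

    The lag is applied as an integer frame shift (``lag_s`` must be a whole
    number of sample periods to within 1e-6); before the recording starts
    theta1 is extended with its initial (rest) value.
    """
    theta = np.asarray(theta_deg, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if theta.shape != t.shape:
        raise ValueError("theta_deg and time_s must have matching lengths")
    if law.lag_s == 0 or theta.size < 2:
        shifted = theta.copy()
    else:
        dt = float(t[1] - t[0])
        k_float = law.lag_s / dt
        k = int(round(k_float))
        if abs(k_float - k) > 1e-6:
            raise ValueError(
                f"lag_s={law.lag_s} is not an integer number of sample "
                f"periods (dt={dt})"
            )
        shifted = np.concatenate([np.full(k, theta[0]), theta[:-k]]) if k else theta.copy()
    if law.saturating:
        s = law.saturation_scale_deg
        shifted = s * np.tanh(shifted / s)
    return law.offset_deg + law.gain(profile) * shifted


def _forward_kinematics(
    mcp_deg: np.ndarray,
    pip_deg: np.ndarray,
    dip_deg: np.ndarray,
    finger_length_mm: float,
    origin: np.ndarray,
) -> np.ndarray:
    """Planar three-link chain in the Y0-Z0 plane -> (n, 4, 3) joint centers.

    The MCP angle is measured from +Z0; PIP/DIP flexion adds to the running
    segment direction (clockwise-positive convention of the joint model).
    """
    n = mcp_deg.shape[0]
    lengths = finger_length_mm * np.asarray(PHALANX_FRACTIONS)
    cum = np.column_stack(
        [mcp_deg, mcp_deg + pip_deg, mcp_deg + pip_deg + dip_deg]
    )
    ang = np.deg2rad(cum)
    pos = np.zeros((n, 4, 3))
    pos[:, 0] = origin
    for j in range(3):
        step = np.column_stack(
            [
                np.zeros(n),
                lengths[j] * np.sin(ang[:, j]),
                lengths[j] * np.cos(ang[:, j]),
            ]
        )
        pos[:, j + 1] = pos[:, j] + step
    return pos


def _session_rng(profile: SubjectProfile, config: GeneratorConfig):
    key = zlib.crc32(profile.subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def generate_session(
    profile: SubjectProfile, config: GeneratorConfig
) -> list[HandTrajectory]:
    """Generate all recording sets for one subject.

    Each set holds ``keystrokes_per_set`` metronome-locked cycles of
    ``cycle_period_s`` sampled at ``sample_rate_hz``. The generating angles
    (theta1 for the middle finger, beta1 from the coupling law for the ring
    finger, plus proportional PIP/DIP flexion) optionally receive Gaussian
    angle-domain noise before forward kinematics; Gaussian position noise may
    be added afterwards. Reproducible per (profile, config, seed).
    """
    rng = _session_rng(profile, config)
    T = config.cycle_period_s
    n = config.frames_per_set
    dt = 1.0 / config.sample_rate_hz
    t = np.arange(n) * dt
    beta_rest = config.coupling.offset_deg + config.coupling.gain(profile) * (
        config.rest_angle_deg
    )

    sets: list[HandTrajectory] = []
    for s in range(config.sets_per_subject):
        theta1 = middle_mcp_profile(
            t % T, T, config.amplitude_deg, config.rest_angle_deg
        )
        beta1 = true_ring_angle(theta1, t, profile, config.coupling)
        theta2 = config.pip_ratio * (theta1 - config.rest_angle_deg)
        theta3 = config.dip_ratio * (theta1 - config.rest_angle_deg)
        beta2 = config.pip_ratio * (beta1 - beta_rest)
        beta3 = config.dip_ratio * (beta1 - beta_rest)

        angles = [theta1, theta2, theta3, beta1, beta2, beta3]
        if config.angle_noise_sd_deg > 0:
            angles = [
                a + rng.normal(0.0, config.angle_noise_sd_deg, n)
                for a in angles
            ]
        theta1, theta2, theta3, beta1, beta2, beta3 = angles

        middle = _forward_kinematics(
            theta1, theta2, theta3, profile.middle_length_mm, np.zeros(3)
        )
        ring = _forward_kinematics(
            beta1, beta2, beta3, profile.ring_length_mm, RING_P0_OFFSET_MM
        )
        positions = np.stack([middle, ring], axis=1)
        if config.position_noise_sd_mm > 0:
            positions = positions + rng.normal(
                0.0, config.position_noise_sd_mm, positions.shape
            )
        sets.append(
            HandTrajectory(
                subject_id=profile.subject_id,
                set_index=s,
                time_s=t.copy(),
                positions=positions,
            )
        )
    return sets


def generate_cohort(
    config: GeneratorConfig,
    population: PopulationParams | None = None,
    profiles: list[SubjectProfile] | None = None,
) -> tuple[list[SubjectProfile], dict[str, list[HandTrajectory]]]:
    """Sample (or accept) a cohort of subjects and generate all sessions."""
    if profiles is None:
        profiles = sample_subjects(config.n_subjects, population, config.seed)
    elif len(profiles) != config.n_subjects:
        config = replace(config, n_subjects=len(profiles))
    sessions = {p.subject_id: generate_session(p, config) for p in profiles}
    return profiles, sessions


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "time_s",
    "subject_id",
    "set_index",
    "finger",
    "joint",
    "x_mm",
    "y_mm",
    "z_mm",
]


def write_trajectory(path, traj: HandTrajectory) -> None:
    """Write one trajectory in the long CSV dialect (one row per
    frame/finger/joint, values to 6 decimal places)."""
    n = traj.n_frames
    frame_idx = np.repeat(np.arange(n), 8)
    finger_idx = np.tile(np.repeat(np.arange(2), 4), n)
    joint_idx = np.tile(np.arange(4), 2 * n)
    xyz = traj.positions[frame_idx, finger_idx, joint_idx]
    df = pd.DataFrame(
        {
            "time_s": traj.time_s[frame_idx],
            "subject_id": traj.subject_id,
            "set_index": traj.set_index,
            "finger": np.asarray(FINGERS)[finger_idx],
            "joint": np.asarray(JOINTS)[joint_idx],
            "x_mm": xyz[:, 0],
            "y_mm": xyz[:, 1],
            "z_mm": xyz[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path) -> HandTrajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Raises :class:`TrajectorySchemaError` on missing columns and
    :class:`TrajectoryParseError` (naming the offending line where possible)
    on malformed values or a non-monotone time column.
    """
    try:
        df = pd.read_csv(path)
    except (ValueError, pd.errors.ParserError) as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectorySchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise TrajectoryParseError(f"{path}: file contains no frames")
    for col in ("time_s", "x_mm", "y_mm", "z_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            # +2: header line plus 1-based numbering
            raise TrajectoryParseError(
                f"{path}: non-numeric value in column {col!r} at line "
                f"{int(bad[0]) + 2}"
            )
        df[col] = vals
    if len(df) % 8 != 0:
        raise TrajectoryParseError(
            f"{path}: row count {len(df)} is not a multiple of 8 "
            "(2 fingers x 4 joints per frame)"
        )
    n = len(df) // 8
    times = df["time_s"].to_numpy()[::8]
    dt = np.diff(times)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        line = int(bad[0] + 1) * 8 + 2
        raise TrajectoryParseError(
            f"{path}: time column is not strictly increasing at line {line}"
        )
    finger_idx = np.array(
        [FINGERS.index(f) for f in df["finger"]], dtype=int
    ).reshape(n, 8)
    joint_idx = np.array(
        [JOINTS.index(j) for j in df["joint"]], dtype=int
    ).reshape(n, 8)
    xyz = df[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(n, 8, 3)
    positions = np.zeros((n, 2, 4, 3))
    for r in range(8):
        positions[np.arange(n), finger_idx[:, r], joint_idx[:, r]] = xyz[:, r]
    return HandTrajectory(
        subject_id=str(df["subject_id"].iloc[0]),
        set_index=int(df["set_index"].iloc[0]),
        time_s=times,
        positions=positions,
    )


def write_manifest(path, profiles: list[SubjectProfile], config: GeneratorConfig) -> None:
    """Cohort manifest JSON: subject profiles + generator configuration."""
    payload = {
        "subjects": [asdict(p) for p in profiles],
        "generator": asdict(config),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
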