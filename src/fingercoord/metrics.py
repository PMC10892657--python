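"""Evaluation metrics and split protocols for the coordination models.

MAE, RMSE and MAPE of predicted vs measured ring-finger MCP angles, the
per-cycle maximum-absolute-error summary used to compare model stability,
and the two split protocols: an order-preserving first-n/rest split over
recording sets (individual scope) and a leave-subject-out split (multi
scope, train on subjects 1..11, test on subject 12).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EvalReport",
    "mae",
    "rmse",
    "mape",
    "per_cycle_max_abs_error",
    "split_per_set",
    "split_leave_subject_out",
    "evaluate_predictions",
]


class MapeValue(float):
    """A MAPE percentage that also records how many frames were excluded
    by the small-denominator floor."""

    n_excluded: int

    def __new__(cls, value: float, n_excluded: int):
        obj = super().__new__(cls, value)
        obj.n_excluded = int(n_excluded)
        return obj


def _check_pair(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("pred and actual must have the same length")
    if p.size == 0:
        raise ValueError("empty error vector")
    return p, a


def mae(pred, actual) -> float:
    """Mean absolute error, degrees."""
    p, a = _check_pair(pred, actual)
    return float(np.mean(np.abs(p - a)))


def rmse(pred, actual) -> float:
    """Root mean square error, degrees."""
    p, a = _check_pair(pred, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def mape(pred, actual, floor_deg: float = 1.0) -> MapeValue:
    """Mean absolute percentage error over frames with |actual| >= floor.

    Angle series pass near the rest angle, so a small-denominator floor
    (default 1 deg) keeps the metric defined; the number of excluded frames
    is carried on the returned value (``.n_excluded``) for auditability.
    """
    if floor_deg <= 0:
        raise ValueError("floor_deg must be positive")
    p, a = _check_pair(pred, actual)
    keep = np.abs(a) >= floor_deg
    if not np.any(keep):
        raise ValueError("all frames below the MAPE denominator floor")
    pct = 100.0 * float(np.mean(np.abs(p[keep] - a[keep]) / np.abs(a[keep])))
    return MapeValue(pct, int(np.sum(~keep)))


def per_cycle_max_abs_error(pred, actual, cycle_bounds) -> np.ndarray:
    """Maximum |pred - actual| within each [start, end) cycle window."""
    p, a = _check_pair(pred, actual)
    err = np.abs(p - a)
    out = np.empty(len(cycle_bounds))
    for k, (start, end) in enumerate(cycle_bounds):
        if end <= start or start < 0 or end > err.size:
            raise ValueError(f"invalid cycle window ({start}, {end})")
        out[k] = err[start:end].max()
    return out


def split_per_set(sets: Sequence, n_train: int) -> tuple[list, list]:
    """Order-preserving prefix/suffix split over recording sets (no
    shuffling): first ``n_train`` sets train, the rest test."""
    if not 0 < n_train < len(sets):
        raise ValueError(
            f"n_train={n_train} must lie strictly between 0 and {len(sets)}"
        )
    return list(sets[:n_train]), list(sets[n_train:])


def split_leave_subject_out(
    cohort: Sequence,
    test_subject_id: str,
    key: Callable = lambda s: s.subject_id,
) -> tuple[list, list]:
    """Hold out every record of one subject; train on the remainder."""
    test = [s for s in cohort if key(s) == test_subject_id]
    if not test:
        raise ValueError(f"unknown subject id {test_subject_id!r}")
    train = [s for s in cohort if key(s) != test_subject_id]
    return train, test


@dataclass
class EvalReport:
    """Metrics for one model variant on one split."""

    model_variant: str
    scope: str
    mae_deg: float
    rmse_deg: float
    mape_pct: float
    per_cycle_max_abs_err_deg: np.ndarray
    split_descriptor: dict = field(default_factory=dict)
    seed: int = 0
    mape_excluded_frames: int = 0

    def __post_init__(self) -> None:
        self.per_cycle_max_abs_err_deg = np.asarray(
            self.per_cycle_max_abs_err_deg, dtype=float
        )
        if self.mae_deg < 0 or self.rmse_deg < self.mae_deg - 1e-12:
            raise ValueError("requires rmse_deg >= mae_deg >= 0")
        if self.mape_pct < 0:
            raise ValueError("mape_pct must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_cycle_max_abs_err_deg"] = self.per_cycle_max_abs_err_deg.tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def evaluate_predictions(
    pred,
    actual,
    cycle_bounds,
    model_variant: str = "bp",
    scope: str = "individual",
    split_descriptor: dict | None = None,
    seed: int = 0,
    mape_floor_deg: float = 1.0,
) -> EvalReport:
    """Assemble a full report for one prediction run."""
    m = mape(pred, actual, mape_floor_deg)
    return EvalReport(
        model_variant=model_variant,
        scope=scope,
        mae_deg=mae(pred, actual),
        rmse_deg=rmse(pred, actual),
        mape_pct=float(m),
        per_cycle_max_abs_err_deg=per_cycle_max_abs_error(
            pred, actual, cycle_bounds
        ),
        split_descriptor=split_descriptor or {},
        seed=seed,
        mape_excluded_frames=m.n_excluded,
    )
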