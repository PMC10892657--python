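"""Single-hidden-layer regression network trained by Levenberg-Marquardt.

The coordination model maps middle-finger MCP kinematics (and, in the
multi-individual variant, subject covariates) to the ring-finger MCP angle:

    y_hat = W2 . tanh(W1 x + b1) + b2

with 13 tanh ("tansig") hidden units and a linear ("purelin") output. The
trainer is full-batch Levenberg-Marquardt on the residual vector: per epoch
it solves (J^T J + mu I) delta = -J^T r with an analytic Jacobian, accepts
the step (mu <- mu * 0.1) when the MSE decreases and otherwise retries with
mu <- mu * 10, so the accepted-step loss history is non-increasing. A
mini-batch gradient-descent trainer (rate 0.01, batch 32) is available via
``TrainConfig.method = "sgd"`` for fidelity experiments.

Features and targets are min-max scaled to [-1, 1] with ranges captured on
the training split; reported errors are always in denormalized degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .kinematics import JointAngleSeries
from .synth import SubjectProfile

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "FeatureMatrix",
    "LMConvergenceError",
    "build_features",
    "feature_ranges",
    "normalize",
    "denormalize",
    "init_params",
    "forward",
    "flatten",
    "unflatten",
    "param_count",
    "residual_jacobian",
    "train_lm",
    "train_sgd",
    "save_model",
    "load_model",
]

HIDDEN_DEFAULT = 13

INDIVIDUAL_COLUMNS = ["theta1_deg", "omega1_deg_s", "alpha1_deg_s2"]
COVARIATE_COLUMNS = ["ring_length_mm", "middle_length_mm", "training_years"]


class LMConvergenceError(RuntimeError):
    """Raised when the damped normal equations cannot be solved at mu_max.

    Carries the best parameters found so far in ``best_params``.
    """

    def __init__(self, message: str, best_params: "NetworkParams"):
        super().__init__(message)
        self.best_params = best_params


@dataclass
class NetworkParams:
    """Weights of the 1-hidden-layer network.

    Flatten order is canonical and shared with the metaheuristic search
    space: row-major W1, then b1, then W2, then b2 —
    dimension = input_dim * hidden + hidden + hidden + 1.
    """

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        h, d = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (h,):
            raise ValueError("inconsistent parameter shapes")
        if not (
            np.all(np.isfinite(self.W1))
            and np.all(np.isfinite(self.b1))
            and np.all(np.isfinite(self.W2))
            and np.isfinite(self.b2)
        ):
            raise ValueError("parameters must be finite")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    seed: int = 0
    method: str = "lm"  # "lm" | "sgd"
    learning_rate: float = 0.01
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not (self.mu_increase > 1.0 and 0.0 < self.mu_decrease < 1.0):
            raise ValueError("mu factors must be > 1 and in (0, 1)")
        if self.method not in ("lm", "sgd"):
            raise ValueError("method must be 'lm' or 'sgd'")


@dataclass
class FeatureMatrix:
    """Design matrix + target for one data split."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    norm_ranges: dict | None = None  # {"x_min","x_max","y_min","y_max"}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts must match")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names do not match X")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.y)):
            raise ValueError("features contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]


def build_features(
    series: JointAngleSeries,
    profile: SubjectProfile | None = None,
    mode: str = "individual",
) -> FeatureMatrix:
    """Assemble the model inputs from one angle series.

    ``individual`` mode yields 3 columns (theta1, omega1, alpha1); ``multi``
    mode appends the constant covariate columns (ring length, middle length,
    training years) and requires a profile. The target is beta1.
    """
    if mode not in ("individual", "multi"):
        raise ValueError("mode must be 'individual' or 'multi'")
    cols = [series.theta1_deg, series.omega1_deg_s, series.alpha1_deg_s2]
    names = list(INDIVIDUAL_COLUMNS)
    if mode == "multi":
        if profile is None:
            raise ValueError("multi mode requires a SubjectProfile")
        n = series.n_frames
        cols += [
            np.full(n, profile.ring_length_mm),
            np.full(n, profile.middle_length_mm),
            np.full(n, profile.training_years),
        ]
        names += list(COVARIATE_COLUMNS)
    X = (
        np.column_stack(cols)
        if series.n_frames
        else np.empty((0, len(names)))
    )
    return FeatureMatrix(X=X, y=np.asarray(series.beta1_deg, float), column_names=names)


def feature_ranges(X: np.ndarray, column_names: list[str] | None = None):
    """Per-column (min, max) captured on the training split."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    degenerate = np.nonzero(hi <= lo)[0]
    if degenerate.size:
        names = (
            [column_names[i] for i in degenerate]
            if column_names
            else degenerate.tolist()
        )
        raise ValueError(f"degenerate (constant) feature columns: {names}")
    return lo, hi


def normalize(X: np.ndarray, lo, hi) -> np.ndarray:
    """Min-max scale to [-1, 1] using training ranges (test values may
    fall outside the interval)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    return 2.0 * (np.asarray(X, float) - lo) / (hi - lo) - 1.0


def denormalize(Xn: np.ndarray, lo, hi) -> np.ndarray:
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    return (np.asarray(Xn, float) + 1.0) * (hi - lo) / 2.0 + lo


def param_count(input_dim: int, hidden_dim: int = HIDDEN_DEFAULT) -> int:
    return input_dim * hidden_dim + hidden_dim + hidden_dim + 1


def init_params(
    input_dim: int,
    hidden_dim: int = HIDDEN_DEFAULT,
    rng: np.random.Generator | int | None = None,
    scale: float = 0.5,
) -> NetworkParams:
    """Uniform [-scale, scale] initialization from a seeded generator."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return NetworkParams(
        W1=rng.uniform(-scale, scale, (hidden_dim, input_dim)),
        b1=rng.uniform(-scale, scale, hidden_dim),
        W2=rng.uniform(-scale, scale, hidden_dim),
        b2=float(rng.uniform(-scale, scale)),
    )


def flatten(params: NetworkParams) -> np.ndarray:
    return np.concatenate(
        [params.W1.ravel(), params.b1, params.W2, [params.b2]]
    )


def unflatten(
    vec: np.ndarray, input_dim: int, hidden_dim: int = HIDDEN_DEFAULT
) -> NetworkParams:
    vec = np.asarray(vec, dtype=float)
    expected = param_count(input_dim, hidden_dim)
    if vec.shape != (expected,):
        raise ValueError(
            f"expected flattened length {expected}, got {vec.shape}"
        )
    h, d = hidden_dim, input_dim
    W1 = vec[: h * d].reshape(h, d)
    b1 = vec[h * d : h * d + h]
    W2 = vec[h * d + h : h * d + 2 * h]
    b2 = float(vec[-1])
    return NetworkParams(W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2)


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Network predictions, one per row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.input_dim:
        raise ValueError(
            f"X has {X.shape[1]} columns, network expects {params.input_dim}"
        )
    A = np.tanh(X @ params.W1.T + params.b1)
    return A @ params.W2 + params.b2


def residual_jacobian(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Jacobian of the residuals (y_hat - y) w.r.t. the flattened parameters.

    Since residuals are y_hat - y, this equals d(y_hat)/d(theta): (n, p).
    Column order matches :func:`flatten`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    h = params.hidden_dim
    A = np.tanh(X @ params.W1.T + params.b1)  # (n, h)
    S = (1.0 - A**2) * params.W2  # (n, h): dy/dz_j
    J = np.empty((n, param_count(d, h)))
    J[:, : h * d] = (S[:, :, None] * X[:, None, :]).reshape(n, h * d)
    J[:, h * d : h * d + h] = S
    J[:, h * d + h : h * d + 2 * h] = A
    J[:, -1] = 1.0
    return J


def _mse(params: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    r = forward(params, X) - y
    return float(np.mean(r * r))


def _solve_damped(JtJ: np.ndarray, g: np.ndarray, mu: float) -> np.ndarray | None:
    A = JtJ + mu * np.eye(JtJ.shape[0])
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
        return scipy.linalg.cho_solve((c, low), g, check_finite=False)
    except scipy.linalg.LinAlgError:
        try:
            return scipy.linalg.lstsq(A, g, check_finite=False)[0]
        except scipy.linalg.LinAlgError:
            return None


def train_lm(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[NetworkParams, list[float]]:
    """Full-batch Levenberg-Marquardt refinement of ``params``.

    Returns the trained parameters and the accepted-step MSE history
    (entry 0 is the initial MSE; the sequence is non-increasing). Stops at
    ``max_epochs``, when the gradient infinity-norm falls below
    ``grad_tol``, or when no step is accepted before mu exceeds ``mu_max``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts must match")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to train")
    if config.method == "sgd":
        return train_sgd(params, X, y, config)

    theta = flatten(params)
    dims = (params.input_dim, params.hidden_dim)
    mu = config.mu_init
    current = unflatten(theta, *dims)
    mse = _mse(current, X, y)
    history = [mse]

    for _ in range(config.max_epochs):
        J = residual_jacobian(current, X)
        r = forward(current, X) - y
        g = J.T @ r  # proportional to the MSE gradient (x n/2)
        if np.max(np.abs(g)) * 2.0 / X.shape[0] < config.grad_tol:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            delta = _solve_damped(JtJ, g, mu)
            if delta is None:
                if mu >= config.mu_max:
                    raise LMConvergenceError(
                        "damped normal equations singular at mu_max",
                        best_params=current,
                    )
                mu *= config.mu_increase
                continue
            candidate = unflatten(theta - delta, *dims)
            new_mse = _mse(candidate, X, y)
            if np.isfinite(new_mse) and new_mse < mse:
                theta = theta - delta
                current = candidate
                mse = new_mse
                mu = max(mu * config.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            break  # mu exhausted without improvement: converged
        history.append(mse)
    return current, history


def train_sgd(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(method="sgd"),
) -> tuple[NetworkParams, list[float]]:
    """Mini-batch gradient descent (fidelity variant: rate 0.01, batch 32).

    The history records the full-batch MSE after each epoch; unlike LM it is
    not guaranteed monotone.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)
    theta = flatten(params)
    dims = (params.input_dim, params.hidden_dim)
    n = X.shape[0]
    current = unflatten(theta, *dims)
    history = [_mse(current, X, y)]
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            J = residual_jacobian(current, X[idx])
            r = forward(current, X[idx]) - y[idx]
            grad = 2.0 * (J.T @ r) / idx.size
            theta = theta - config.learning_rate * grad
            current = unflatten(theta, *dims)
        history.append(_mse(current, X, y))
    return current, history


def save_model(path, params: NetworkParams, norm_ranges: dict | None = None,
               metadata: dict | None = None) -> None:
    """JSON serialization: dims, flattened weights, ranges, metadata."""
    payload = {
        "format_version": "fingercoord-model-1",
        "input_dim": params.input_dim,
        "hidden_dim": params.hidden_dim,
        "weights": flatten(params).tolist(),
        "norm_ranges": {
            k: np.asarray(v, float).tolist() for k, v in (norm_ranges or {}).items()
        },
        "metadata": metadata or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[NetworkParams, dict, dict]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    params = unflatten(
        np.asarray(payload["weights"], float),
        payload["input_dim"],
        payload["hidden_dim"],
    )
    ranges = {
        k: np.asarray(v, float) for k, v in payload.get("norm_ranges", {}).items()
    }
    return params, ranges, payload.get("metadata", {})
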