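"""GA and sparrow-search initialization of the network's weights.

Gradient refinement of a tanh network is sensitive to its starting point, so
the GA-BP / SSA-BP variants first search the flattened weight space with a
population metaheuristic whose fitness is the candidate's *untrained*
forward-pass MSE on the training split, then hand the best vector to the
Levenberg-Marquardt trainer.

The genetic algorithm is real-coded: tournament selection (size 2),
whole-arithmetic crossover, per-gene Gaussian mutation (SD = 0.1 x bound
range) and 1-elitism. The sparrow search algorithm follows the canonical
explorer/follower/vigilante update rules (Xue & Shen, 2020): explorers decay
multiplicatively while the alarm value is below the safety threshold and
take Gaussian steps otherwise; followers either exploit the best explorer or
disperse when ranked in the worse half; a random subset of vigilantes steps
toward the global best (or jitters in place when already there). All
candidates are clipped to the search bounds; both optimizers are
deterministic per seed and track a non-increasing best-so-far history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import (
    FeatureMatrix,
    NetworkParams,
    TrainConfig,
    HIDDEN_DEFAULT,
    forward,
    init_params,
    param_count,
    train_lm,
    unflatten,
)

__all__ = [
    "GAConfig",
    "SSAConfig",
    "OptimizationResult",
    "fitness_mse",
    "make_fitness",
    "ga_optimize",
    "ssa_optimize",
    "seeded_training",
]

VARIANTS = ("bp", "ga-bp", "ssa-bp")


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 50
    n_generations: int = 100
    p_crossover: float = 0.6
    p_mutation: float = 0.2
    bounds: tuple[float, float] = (-3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.pop_size % 2:
            raise ValueError("pop_size must be an even integer >= 2")
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy low < high")


@dataclass(frozen=True)
class SSAConfig:
    pop_size: int = 50
    n_iterations: int = 100
    explorer_ratio: float = 0.7
    vigilante_ratio: float = 0.2
    safety_threshold: float = 0.8
    bounds: tuple[float, float] = (-3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        for name in ("explorer_ratio", "vigilante_ratio"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy low < high")


@dataclass
class OptimizationResult:
    best_vector: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness, initial population included
    mean_history: np.ndarray  # population mean fitness per iteration
    evaluations: int

    def __post_init__(self) -> None:
        self.history = np.asarray(self.history, dtype=float)
        if np.any(np.diff(self.history) > 0):
            raise ValueError("best-so-far history must be non-increasing")
        if self.history.size and self.best_fitness != self.history[-1]:
            raise ValueError("best_fitness must equal the last history entry")


def fitness_mse(
    candidate: np.ndarray,
    features: FeatureMatrix,
    hidden_dim: int = HIDDEN_DEFAULT,
) -> float:
    """MSE of the candidate weight vector's forward pass on ``features``.

    No gradient steps happen inside the fitness; the metaheuristic scores
    raw initial weights only.
    """
    d = features.X.shape[1]
    if np.asarray(candidate).shape != (param_count(d, hidden_dim),):
        raise ValueError(
            f"candidate length {np.asarray(candidate).size} does not match "
            f"a {d}-input, {hidden_dim}-hidden network"
        )
    params = unflatten(candidate, d, hidden_dim)
    r = forward(params, features.X) - features.y
    return float(np.mean(r * r))


def make_fitness(
    features: FeatureMatrix, hidden_dim: int = HIDDEN_DEFAULT
) -> Callable[[np.ndarray], float]:
    return lambda vec: fitness_mse(vec, features, hidden_dim)


def _evaluate(fitness, pop: np.ndarray) -> np.ndarray:
    return np.array([fitness(ind) for ind in pop])


def ga_optimize(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    config: GAConfig = GAConfig(),
) -> OptimizationResult:
    """Real-coded genetic algorithm over ``dim`` box-bounded variables."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    low, high = config.bounds
    sigma = 0.1 * (high - low)
    pop = rng.uniform(low, high, (config.pop_size, dim))
    fit = _evaluate(fitness, pop)
    evaluations = config.pop_size
    best_idx = int(np.argmin(fit))
    best_vec = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]
    mean_history = [float(np.mean(fit))]

    for _ in range(config.n_generations):
        # tournament-2 selection of parents
        a = rng.integers(config.pop_size, size=config.pop_size)
        b = rng.integers(config.pop_size, size=config.pop_size)
        winners = np.where(fit[a] <= fit[b], a, b)
        parents = pop[winners]
        children = parents.copy()
        for i in range(0, config.pop_size - 1, 2):
            if rng.random() < config.p_crossover:
                u = rng.random()
                p1, p2 = parents[i].copy(), parents[i + 1].copy()
                children[i] = u * p1 + (1 - u) * p2
                children[i + 1] = (1 - u) * p1 + u * p2
        mask = rng.random(children.shape) < config.p_mutation
        children = children + mask * rng.normal(0.0, sigma, children.shape)
        np.clip(children, low, high, out=children)
        # 1-elitism: carry the incumbent, fitness already known
        children[0] = best_vec
        child_fit = _evaluate(fitness, children[1:])
        evaluations += config.pop_size - 1
        fit = np.concatenate([[best_fit], child_fit])
        pop = children
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_vec = pop[gen_best].copy()
        history.append(best_fit)
        mean_history.append(float(np.mean(fit)))

    return OptimizationResult(
        best_vector=best_vec,
        best_fitness=best_fit,
        history=np.array(history),
        mean_history=np.array(mean_history),
        evaluations=evaluations,
    )


def ssa_optimize(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    config: SSAConfig = SSAConfig(),
) -> OptimizationResult:
    """Canonical sparrow search algorithm over box-bounded variables."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    low, high = config.bounds
    n = config.pop_size
    n_explorers = max(1, int(round(config.explorer_ratio * n)))
    n_vigilantes = max(1, int(round(config.vigilante_ratio * n)))
    pop = rng.uniform(low, high, (n, dim))
    fit = _evaluate(fitness, pop)
    evaluations = n
    gbest_idx = int(np.argmin(fit))
    gbest_vec = pop[gbest_idx].copy()
    gbest_fit = float(fit[gbest_idx])
    history = [gbest_fit]
    mean_history = [float(np.mean(fit))]
    eps = np.finfo(float).tiny

    for it in range(1, config.n_iterations + 1):
        order = np.argsort(fit)
        pop = pop[order]
        fit = fit[order]
        worst = pop[-1].copy()
        f_best_iter = fit[0]
        f_worst = fit[-1]

        # explorers (producers)
        R2 = rng.random()  # alarm value, shared within the iteration
        for i in range(n_explorers):
            if R2 < config.safety_threshold:
                alpha = rng.random() * (1 - eps) + eps  # (0, 1]
                pop[i] = pop[i] * np.exp(-(i + 1) / (alpha * config.n_iterations))
            else:
                Q = rng.normal()
                pop[i] = pop[i] + Q  # Q * L, L = ones vector
        best_explorer = pop[0].copy()

        # followers (scroungers)
        for i in range(n_explorers, n):
            if i > n / 2:
                Q = rng.normal()
                pop[i] = Q * np.exp((worst - pop[i]) / (i + 1) ** 2)
            else:
                # step along A+ = A^T (A A^T)^-1 with A a random +-1 row
                # vector; reduces to the mean signed distance to the best
                # explorer, added to every coordinate
                signs = rng.choice([-1.0, 1.0], size=dim)
                step = np.sum(np.abs(pop[i] - best_explorer) * signs) / dim
                pop[i] = best_explorer + step

        # vigilantes (aware of danger), random subset of the population
        watch = rng.choice(n, size=n_vigilantes, replace=False)
        for i in watch:
            beta = rng.normal()
            if fit[i] > f_best_iter:
                pop[i] = gbest_vec + beta * np.abs(pop[i] - gbest_vec)
            else:
                K = rng.uniform(-1.0, 1.0)
                pop[i] = pop[i] + K * (
                    np.abs(pop[i] - worst) / (fit[i] - f_worst + 1e-50)
                )

        np.clip(pop, low, high, out=pop)
        fit = _evaluate(fitness, pop)
        evaluations += n
        it_best = int(np.argmin(fit))
        if fit[it_best] < gbest_fit:
            gbest_fit = float(fit[it_best])
            gbest_vec = pop[it_best].copy()
        history.append(gbest_fit)
        mean_history.append(float(np.mean(fit)))

    return OptimizationResult(
        best_vector=gbest_vec,
        best_fitness=gbest_fit,
        history=np.array(history),
        mean_history=np.array(mean_history),
        evaluations=evaluations,
    )


def seeded_training(
    features: FeatureMatrix,
    variant: str,
    net_config: TrainConfig = TrainConfig(),
    meta_config: GAConfig | SSAConfig | None = None,
    hidden_dim: int = HIDDEN_DEFAULT,
    fitness_features: FeatureMatrix | None = None,
) -> tuple[NetworkParams, list[float], OptimizationResult | None]:
    """Train one model variant: plain BP, GA-BP or SSA-BP.

    ``bp`` draws random initial weights; the metaheuristic variants search
    for them first (fitness = forward-pass MSE, optionally on the reduced
    ``fitness_features``), then all variants refine with Levenberg-Marquardt
    on ``features``. Returns (trained params, loss history, optimizer
    result or None).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    d = features.X.shape[1]
    opt_result = None
    if variant == "bp":
        params = init_params(d, hidden_dim, rng=net_config.seed)
    else:
        fit_feats = fitness_features if fitness_features is not None else features
        fitness = make_fitness(fit_feats, hidden_dim)
        dim = param_count(d, hidden_dim)
        if variant == "ga-bp":
            cfg = meta_config or GAConfig(seed=net_config.seed)
            opt_result = ga_optimize(fitness, dim, cfg)
        else:
            cfg = meta_config or SSAConfig(seed=net_config.seed)
            opt_result = ssa_optimize(fitness, dim, cfg)
        params = unflatten(opt_result.best_vector, d, hidden_dim)
    trained, history = train_lm(params, features.X, features.y, net_config)
    return trained, history, opt_result
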