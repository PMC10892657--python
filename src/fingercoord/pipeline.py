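"""End-to-end experiment orchestration.

Reproduces the study's two experiment designs on synthetic cohorts:

* individual scope — one subject, many recording sets, order-preserving
  first-n/rest split (the protocol collects 100 sets of 25 keystrokes and
  trains on the first 80);
* multi scope — a cohort of subjects with covariates, leave-subject-out
  split (train on subjects 1..n-1, test on the held-out last subject).

Each stage receives a seed derived deterministically from the master seed
and the stage name, so adding a model variant never perturbs the data or
the other variants' results.

Training problem sizes are kept desk-scale: Levenberg-Marquardt runs on a
uniform deterministic decimation of the training frames
(``max_train_frames``) and the metaheuristic fitness on a further decimation
(``fitness_frames``); evaluation always uses every test frame.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics, metrics, network, optimizers, synth

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "derive_seed",
    "preset",
    "run_experiment",
    "cmd_simulate",
    "cmd_experiment",
    "individual_protocol_report",
    "multi_protocol_rmse",
]

#: reference participant for the individual-scope protocol
INDIVIDUAL_SUBJECT = synth.SubjectProfile(
    subject_id="data01",
    middle_length_mm=84.8,
    ring_length_mm=80.3,
    training_years=10.0,
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from a master seed + stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    generator: synth.GeneratorConfig = field(
        default_factory=synth.GeneratorConfig
    )
    population: synth.PopulationParams = field(
        default_factory=synth.PopulationParams
    )
    net: network.TrainConfig = field(
        default_factory=lambda: network.TrainConfig(max_epochs=100)
    )
    ga: optimizers.GAConfig = field(default_factory=optimizers.GAConfig)
    ssa: optimizers.SSAConfig = field(default_factory=optimizers.SSAConfig)
    scope: str = "multi"
    variants: tuple[str, ...] = ("bp", "ga-bp", "ssa-bp")
    output_dir: str | None = None
    master_seed: int = 0
    smoothing_window: int = 5
    n_train_sets: int = 80
    test_subject_id: str | None = None
    max_train_frames: int = 30000
    fitness_frames: int = 8000
    fixed_profiles: tuple[synth.SubjectProfile, ...] | None = None

    def __post_init__(self) -> None:
        if self.scope not in ("individual", "multi"):
            raise ValueError("scope must be 'individual' or 'multi'")
        if not self.variants:
            raise ValueError("variants must be nonempty")
        for v in self.variants:
            if v not in optimizers.VARIANTS:
                raise ValueError(f"unknown variant {v!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def preset(name: str, master_seed: int = 0, **overrides) -> ExperimentConfig:
    """Named experiment presets.

    ``smoke`` — tiny sanity-scale run; ``paper-individual`` — single subject,
    100 sets x 25 keystrokes, first-80/last-20 split, plain BP;
    ``paper-multi`` — 12 subjects x 30 sets x 25 keystrokes,
    leave-last-subject-out, all three variants.
    """
    if name == "smoke":
        cfg = ExperimentConfig(
            generator=synth.GeneratorConfig(
                n_subjects=2, sets_per_subject=2, keystrokes_per_set=5
            ),
            scope="individual",
            variants=("bp",),
            n_train_sets=1,
            master_seed=master_seed,
        )
    elif name == "paper-individual":
        cfg = ExperimentConfig(
            generator=synth.GeneratorConfig(
                n_subjects=1, sets_per_subject=100, keystrokes_per_set=25
            ),
            scope="individual",
            variants=("bp",),
            n_train_sets=80,
            fixed_profiles=(INDIVIDUAL_SUBJECT,),
            master_seed=master_seed,
        )
    elif name == "paper-multi":
        cfg = ExperimentConfig(
            generator=synth.GeneratorConfig(
                n_subjects=12, sets_per_subject=30, keystrokes_per_set=25
            ),
            scope="multi",
            variants=("bp", "ga-bp", "ssa-bp"),
            master_seed=master_seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    profiles: list[synth.SubjectProfile]
    reports: dict[str, metrics.EvalReport]
    loss_histories: dict[str, list[float]]
    optimizer_results: dict[str, optimizers.OptimizationResult | None]

    def aggregate(self) -> pd.DataFrame:
        """Table-style summary: one row per variant."""
        rows = [
            {
                "model": v,
                "mae_deg": r.mae_deg,
                "rmse_deg": r.rmse_deg,
                "mape_pct": r.mape_pct,
            }
            for v, r in self.reports.items()
        ]
        return pd.DataFrame(rows)


def _decimate(n: int, target: int) -> np.ndarray:
    """Deterministic uniform decimation indices (no RNG involved)."""
    if n <= target:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, target).astype(int))


def _cohort(config: ExperimentConfig):
    gen = replace(
        config.generator, seed=derive_seed(config.master_seed, "generate")
    )
    profiles = list(config.fixed_profiles) if config.fixed_profiles else None
    if profiles is not None and len(profiles) != gen.n_subjects:
        gen = replace(gen, n_subjects=len(profiles))
    return synth.generate_cohort(gen, config.population, profiles), gen


def _angle_sets(
    sessions: dict[str, list[synth.HandTrajectory]],
    config: ExperimentConfig,
    gen: synth.GeneratorConfig,
) -> dict[str, list[kinematics.JointAngleSeries]]:
    out: dict[str, list[kinematics.JointAngleSeries]] = {}
    for sid, sets in sessions.items():
        out[sid] = [
            kinematics.segment_cycles(
                kinematics.extract_angles(t, config.smoothing_window),
                gen.cycle_period_s,
            )
            for t in sets
        ]
    return out


def _stack_features(
    items: list[tuple[kinematics.JointAngleSeries, synth.SubjectProfile]],
    scope: str,
) -> tuple[network.FeatureMatrix, list[tuple[int, int]]]:
    mats, bounds, offset = [], [], 0
    mode = "individual" if scope == "individual" else "multi"
    for series, profile in items:
        fm = network.build_features(series, profile, mode)
        mats.append(fm)
        bounds.extend(
            (a + offset, b + offset) for a, b in series.cycle_bounds
        )
        offset += series.n_frames
    X = np.vstack([m.X for m in mats])
    y = np.concatenate([m.y for m in mats])
    return (
        network.FeatureMatrix(X=X, y=y, column_names=mats[0].column_names),
        bounds,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate -> extract -> train each variant -> evaluate on the split."""
    (profiles, sessions), gen = _cohort(config)
    angles = _angle_sets(sessions, config, gen)
    by_id = {p.subject_id: p for p in profiles}

    if config.scope == "individual":
        sid = profiles[0].subject_id
        train_sets, test_sets = metrics.split_per_set(
            angles[sid], config.n_train_sets
        )
        profile = by_id[sid]
        train_items = [(s, profile) for s in train_sets]
        test_items = [(s, profile) for s in test_sets]
        split_desc = {
            "protocol": "per-set",
            "subject": sid,
            "n_train_sets": config.n_train_sets,
            "n_test_sets": len(test_sets),
        }
    else:
        test_sid = config.test_subject_id or profiles[-1].subject_id
        train_profiles, test_profiles = metrics.split_leave_subject_out(
            profiles, test_sid
        )
        train_items = [
            (s, p) for p in train_profiles for s in angles[p.subject_id]
        ]
        test_items = [
            (s, p) for p in test_profiles for s in angles[p.subject_id]
        ]
        split_desc = {
            "protocol": "leave-subject-out",
            "test_subject": test_sid,
            "n_train_subjects": len(train_profiles),
        }
    split_desc["smoothing_window"] = config.smoothing_window
    split_desc["metric_basis"] = "frames"

    train_fm, _ = _stack_features(train_items, config.scope)
    test_fm, test_bounds = _stack_features(test_items, config.scope)

    x_lo, x_hi = network.feature_ranges(train_fm.X, train_fm.column_names)
    y_lo, y_hi = float(train_fm.y.min()), float(train_fm.y.max())
    if y_hi <= y_lo:
        raise ValueError("degenerate target range on the training split")

    Xn_train = network.normalize(train_fm.X, x_lo, x_hi)
    yn_train = network.normalize(train_fm.y, y_lo, y_hi)
    Xn_test = network.normalize(test_fm.X, x_lo, x_hi)

    keep = _decimate(Xn_train.shape[0], config.max_train_frames)
    fit_keep = keep[_decimate(keep.size, config.fitness_frames)]
    lm_features = network.FeatureMatrix(
        X=Xn_train[keep], y=yn_train[keep], column_names=train_fm.column_names
    )
    fit_features = network.FeatureMatrix(
        X=Xn_train[fit_keep],
        y=yn_train[fit_keep],
        column_names=train_fm.column_names,
    )

    reports: dict[str, metrics.EvalReport] = {}
    histories: dict[str, list[float]] = {}
    opt_results: dict[str, optimizers.OptimizationResult | None] = {}
    for variant in config.variants:
        seed = derive_seed(config.master_seed, f"train:{variant}")
        net_cfg = replace(config.net, seed=seed)
        meta_cfg = None
        if variant == "ga-bp":
            meta_cfg = replace(config.ga, seed=seed)
        elif variant == "ssa-bp":
            meta_cfg = replace(config.ssa, seed=seed)
        params, history, opt = optimizers.seeded_training(
            lm_features,
            variant,
            net_cfg,
            meta_cfg,
            fitness_features=fit_features,
        )
        pred = network.denormalize(
            network.forward(params, Xn_test), y_lo, y_hi
        )
        reports[variant] = metrics.evaluate_predictions(
            pred,
            test_fm.y,
            test_bounds,
            model_variant=variant,
            scope=config.scope,
            split_descriptor=split_desc,
            seed=config.master_seed,
        )
        histories[variant] = history
        opt_results[variant] = opt

    return ExperimentResult(
        config=config,
        profiles=profiles,
        reports=reports,
        loss_histories=histories,
        optimizer_results=opt_results,
    )


def cmd_simulate(config: ExperimentConfig) -> dict:
    """Generate a cohort and write it to ``output_dir``.

    Writes one trajectory CSV per recording set plus a cohort manifest JSON;
    byte-identical across reruns with the same configuration and seed.
    Returns a summary dict including the total keystroke-cycle count.
    """
    if config.output_dir is None:
        raise ValueError("cmd_simulate requires output_dir")
    out = Path(config.output_dir)
    (out / "trajectories").mkdir(parents=True, exist_ok=True)
    (profiles, sessions), gen = _cohort(config)
    n_cycles = 0
    paths = []
    for p in profiles:
        for traj in sessions[p.subject_id]:
            series = kinematics.segment_cycles(
                kinematics.extract_angles(traj), gen.cycle_period_s
            )
            n_cycles += len(series.cycle_bounds)
            path = (
                out
                / "trajectories"
                / f"{p.subject_id}_set{traj.set_index:03d}.csv"
            )
            synth.write_trajectory(path, traj)
            paths.append(str(path))
    synth.write_manifest(out / "manifest.json", profiles, gen)
    summary = {
        "n_subjects": len(profiles),
        "n_sets": sum(len(s) for s in sessions.values()),
        "n_cycles": n_cycles,
        "config_hash": config.config_hash(),
        "seed": gen.seed,
        "paths": paths,
    }
    with open(out / "simulate_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def cmd_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full experiment and write reports/artifacts to output_dir."""
    result = run_experiment(config)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "stage_seeds": {
                "generate": derive_seed(config.master_seed, "generate"),
                **{
                    f"train:{v}": derive_seed(
                        config.master_seed, f"train:{v}"
                    )
                    for v in config.variants
                },
            },
        }
        for variant, report in result.reports.items():
            d = report.to_dict()
            d["provenance"] = stamp
            with open(out / f"report_{variant}.json", "w", encoding="utf-8") as fh:
                json.dump(d, fh, indent=2)
            opt = result.optimizer_results[variant]
            if opt is not None:
                pd.DataFrame(
                    {
                        "iteration": np.arange(len(opt.history)),
                        "best_fitness": opt.history,
                        "mean_fitness": opt.mean_history,
                    }
                ).to_csv(out / f"optimizer_{variant}.csv", index=False)
        agg = result.aggregate()
        agg.insert(0, "config_hash", stamp["config_hash"])
        agg.to_csv(out / "aggregate.csv", index=False)
    return result


def individual_protocol_report(master_seed: int = 0, **overrides) -> metrics.EvalReport:
    """Single-subject protocol: 100 sets x 25 keystrokes, first-80/last-20
    split, plain BP model. Returns the evaluation report."""
    cfg = preset("paper-individual", master_seed=master_seed, **overrides)
    return run_experiment(cfg).reports["bp"]


def multi_protocol_rmse(
    master_seeds=(0, 1, 2), variant: str = "ssa-bp", **overrides
) -> tuple[float, list[metrics.EvalReport]]:
    """Multi-individual protocol: 12 subjects x 30 sets, leave-last-out,
    one variant, averaged over master seeds. Returns (mean RMSE, reports)."""
    reports = []
    for ms in master_seeds:
        cfg = preset(
            "paper-multi", master_seed=ms, variants=(variant,), **overrides
        )
        reports.append(run_experiment(cfg).reports[variant])
    return float(np.mean([r.rmse_deg for r in reports])), reports
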