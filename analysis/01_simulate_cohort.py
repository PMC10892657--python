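#!/usr/bin/env python
"""Simulate a synthetic keystroke cohort and write it to disk.

Generates the 12-subject protocol (30 sets x 25 keystrokes per subject by
default, one 0.75 s cycle per keystroke at 100 Hz), writes one trajectory
CSV per recording set plus a cohort manifest, and prints the realized
counts. Use ``--sets`` / ``--keystrokes`` to scale down for a quick look.
"""

import argparse

from fingercoord import pipeline, synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/cohort")
    ap.add_argument("--subjects", type=int, default=12)
    ap.add_argument("--sets", type=int, default=30)
    ap.add_argument("--keystrokes", type=int, default=25)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = pipeline.ExperimentConfig(
        generator=synth.GeneratorConfig(
            n_subjects=args.subjects,
            sets_per_subject=args.sets,
            keystrokes_per_set=args.keystrokes,
        ),
        output_dir=args.out,
        master_seed=args.seed,
    )
    summary = pipeline.cmd_simulate(cfg)
    print(
        f"wrote {summary['n_subjects']} subjects, {summary['n_sets']} sets, "
        f"{summary['n_cycles']} keystroke cycles to {args.out}"
    )
    print(f"config hash {summary['config_hash']}, generator seed {summary['seed']}")


if __name__ == "__main__":
    main()
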