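#!/usr/bin/env python
"""Simulate the reference-scale kinase yeast-array screen.

Generates the four interchange tables (long spot scores, constructs,
conditions, annotations) for 266 kinases + 80 controls in four strains
across 73 conditions, together with the planted truth (latent activity
tiers, toxic conditions), and validates the emitted dataset.

Writes results/screen/{scores,constructs,conditions,annotations}.tsv and
truth.json.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from kinarray import screen_model as sm
from kinarray.synthetic_screen import SimConfig, simulate_screen

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "screen")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = SimConfig(seed=args.seed)
    dataset, truth = simulate_screen(config)

    sm.write_screen_long(dataset.scores, args.out / "scores.tsv")
    sm.write_constructs(dataset.constructs, args.out / "constructs.tsv")
    sm.write_conditions(dataset.conditions, args.out / "conditions.tsv")
    sm.write_annotations(dataset.annotations, args.out / "annotations.tsv")
    (args.out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))

    report = sm.validate_dataset(
        dataset.scores, dataset.constructs, dataset.conditions, dataset.annotations
    )
    n_kinases = int((~dataset.annotations["is_control"]).sum())
    n_controls = int(dataset.annotations["is_control"].sum())
    n_toxic = sum(truth.condition_toxic.values())
    print(f"simulated screen (seed {args.seed}):")
    print(f"  {n_kinases} kinases + {n_controls} controls, "
          f"{dataset.conditions.shape[0]} conditions ({n_toxic} planted toxic), "
          f"{dataset.scores['strain'].nunique()} strains")
    print(f"  {len(dataset.scores):,} scored spots")
    print(f"  dataset validation: {'clean' if report.ok else report.issues}")
    print(f"  tables written to {args.out}")


if __name__ == "__main__":
    main()
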