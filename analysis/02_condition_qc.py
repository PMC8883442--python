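#!/usr/bin/env python
"""Condition quality control of the simulated screen.

Aggregates spot scores to the kinase level, counts defective kinases per
condition-strain pair, locates the bimodal valley of the count distribution,
excludes globally toxic pairs (> 175 defective kinases), and reports the
evaluable accounting.  Compares the excluded set against the planted toxic
conditions.

Reads results/screen/, writes results/condition_qc.tsv, results/matrix.tsv
and results/qc_summary.json.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from kinarray import condition_qc as qc
from kinarray import screen_model as sm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen", type=Path, default=ROOT / "results" / "screen")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--defect-min-score", type=int, default=1)
    parser.add_argument("--max-defect", type=int, default=qc.DEFAULT_MAX_DEFECT)
    args = parser.parse_args()

    scores = sm.read_screen_long(args.screen / "scores.tsv")
    constructs = sm.read_constructs(args.screen / "constructs.tsv")
    conditions = sm.read_conditions(args.screen / "conditions.tsv")
    annotations = sm.read_annotations(args.screen / "annotations.tsv")
    truth = json.loads((args.screen / "truth.json").read_text())

    matrix = sm.aggregate_to_kinase(scores, constructs, rule="max")
    matrix.to_csv(args.out / "matrix.tsv", sep="\t", index=False)

    counts = qc.defect_counts(
        matrix, args.defect_min_score, "kinases_only", annotations
    )
    valley = qc.detect_valley(counts["n_defect"])
    retained, excluded = qc.filter_conditions(counts, max_defect=args.max_defect)
    summary = qc.evaluable_accounting(conditions, retained)

    flagged = pd.concat([retained, excluded]).sort_values(["condition_id", "strain"])
    flagged.to_csv(args.out / "condition_qc.tsv", sep="\t", index=False)

    toxic = {c for c, flag in truth["condition_toxic"].items() if flag}
    excluded_conditions = set(excluded["condition_id"])
    out = {
        "n_pairs_retained": summary.n_pairs,
        "n_pairs_excluded": int(len(excluded)),
        "per_strain": summary.per_strain,
        "n_conditions_shared_all_strains": summary.n_shared,
        "valley_estimate": valley,
        "threshold_used": args.max_defect,
        "planted_toxic_recovered": sorted(excluded_conditions) == sorted(toxic),
    }
    (args.out / "qc_summary.json").write_text(json.dumps(out, indent=1))

    print("condition QC:")
    print(f"  defect-count valley estimate: {valley} (threshold used: {args.max_defect})")
    print(f"  retained {summary.n_pairs} condition-strain pairs "
          f"({len(excluded)} excluded as globally toxic)")
    print(f"  per strain: {summary.per_strain}")
    print(f"  conditions retained in every strain: {summary.n_shared}")
    print(f"  excluded set equals planted toxic set: {out['planted_toxic_recovered']}")


if __name__ == "__main__":
    main()
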