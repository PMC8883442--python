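#!/usr/bin/env python
"""Phenotype-rate comparisons between protein groups.

For each retained condition-strain pair, computes the fraction of group
members with a growth phenotype and compares distributions across pairs
with the rank-sum test: kinases vs control proteins (any phenotype), and
tyrosine / S-T-ortholog / S-T-non-ortholog classes (severe phenotypes).

Writes results/group_comparison.tsv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from kinarray import group_stats as gs
from kinarray import screen_model as sm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen", type=Path, default=ROOT / "results" / "screen")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--strong-severity", type=int, default=3,
                        help="score counted as a strong phenotype for class comparisons")
    args = parser.parse_args()

    matrix = pd.read_csv(args.out / "matrix.tsv", sep="\t")
    flagged = pd.read_csv(args.out / "condition_qc.tsv", sep="\t")
    annotations = sm.read_annotations(args.screen / "annotations.tsv")
    retained = flagged[~flagged["excluded"]]
    pairs = set(zip(retained["condition_id"], retained["strain"]))

    reports = []

    fractions = gs.group_fractions(
        matrix, annotations, "kinase_vs_control", severity=1, retained_pairs=pairs
    )
    report = gs.compare_groups(fractions, [("kinase", "control")], alternative="greater")
    report["comparison"] = "kinase_vs_control_any_phenotype"
    reports.append(report)

    fractions = gs.group_fractions(
        matrix, annotations, "ortholog_classes",
        severity=args.strong_severity, retained_pairs=pairs,
    )
    report = gs.compare_groups(
        fractions,
        [("tyrosine", "st_non_ortholog"), ("st_ortholog", "st_non_ortholog"),
         ("tyrosine", "st_ortholog")],
        alternative="greater",
    )
    report["comparison"] = "ortholog_classes_strong_phenotype"
    reports.append(report)

    table = pd.concat(reports, ignore_index=True)
    table.to_csv(args.out / "group_comparison.tsv", sep="\t", index=False)

    print("group comparisons (one-sided rank-sum on per-pair fractions):")
    for _, row in table.iterrows():
        print(f"  {row['group_a']} vs {row['group_b']}: medians "
              f"{row['median_a']:.3f} vs {row['median_b']:.3f}, "
              f"U={row['U']:.0f}, p={row['p_value']:.2e}  [{row['comparison']}]")


if __name__ == "__main__":
    main()
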