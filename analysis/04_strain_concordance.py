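#!/usr/bin/env python
"""Cross-strain concordance of growth-defect calls.

Builds per-strain sets of (kinase, condition) defect pairs over the retained
condition-strain pairs, decomposes them by exact strain combination (upset
counts, computed both pre- and post-QC since the reference total could be
either), and histograms kinases by the number of strains with a severe
(score 3) defect.

Writes results/upset_counts.tsv and results/severe_histogram.tsv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from kinarray import screen_model as sm
from kinarray import strain_concordance as sc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen", type=Path, default=ROOT / "results" / "screen")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    matrix = pd.read_csv(args.out / "matrix.tsv", sep="\t")
    flagged = pd.read_csv(args.out / "condition_qc.tsv", sep="\t")
    annotations = sm.read_annotations(args.screen / "annotations.tsv")

    kinases = set(annotations.loc[~annotations["is_control"], "protein_id"])
    kmatrix = matrix[matrix["protein_id"].isin(kinases)]
    retained = flagged[~flagged["excluded"]]
    post_qc = set(zip(retained["condition_id"], retained["strain"]))
    pre_qc = set(zip(flagged["condition_id"], flagged["strain"]))
    strains = sorted(flagged["strain"].unique())

    tables = []
    for label, pairs in (("post_qc", post_qc), ("pre_qc", pre_qc)):
        sets = sc.defect_pair_sets(kmatrix, pairs, defect_min_score=1)
        counts = sc.upset_counts(sets)
        table = sc.upset_table(counts, strains).assign(condition_set=label)
        tables.append(table)
        total = sum(counts.values())
        all_four = counts.get(frozenset(strains), 0)
        one_only = sum(c for combo, c in counts.items() if len(combo) == 1)
        print(f"upset ({label}): {total} defect pairs in >=1 strain; "
              f"{one_only} in exactly one strain; {all_four} in all {len(strains)}")
    pd.concat(tables, ignore_index=True).to_csv(
        args.out / "upset_counts.tsv", sep="\t", index=False
    )

    hist = sc.severe_strain_histogram(kmatrix, post_qc)
    pd.DataFrame(
        {"n_strains": list(hist), "n_kinases": list(hist.values())}
    ).to_csv(args.out / "severe_histogram.tsv", sep="\t", index=False)
    ordered = {k: hist.get(k, 0) for k in sorted(hist, reverse=True)}
    print(f"kinases with severe defects by strain breadth (post-QC): {ordered}")


if __name__ == "__main__":
    main()
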