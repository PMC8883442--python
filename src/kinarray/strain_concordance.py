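"""Cross-strain agreement of growth-defect calls.

Two views: an upset decomposition of (kinase, condition) defect pairs by the
exact combination of strains in which the defect appears, and a per-kinase
histogram over the number of strains showing a *severe* defect (score 3 in
at least one retained condition).  A condition contributes for a strain only
when it was evaluated and retained there, so an unevaluated condition can
never create apparent disagreement.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd


def defect_pair_sets(
    matrix: pd.DataFrame,
    retained_pairs: set[tuple[str, str]],
    defect_min_score: int = 1,
) -> dict[str, set[tuple[str, str]]]:
    """Per strain, the set of (protein, condition) pairs with a defect."""
    strains = sorted({s for _, s in retained_pairs})
    sets: dict[str, set[tuple[str, str]]] = {s: set() for s in strains}
    keep = [
        (cond, strain) in retained_pairs
        for cond, strain in zip(matrix["condition_id"], matrix["strain"])
    ]
    df = matrix[pd.Series(keep, index=matrix.index).to_numpy()]
    df = df[df["score"] >= defect_min_score]
    for protein, strain, cond in zip(df["protein_id"], df["strain"], df["condition_id"]):
        if strain in sets:
            sets[strain].add((protein, cond))
    return sets


def upset_counts(sets: dict[str, set[tuple[str, str]]]) -> dict[frozenset[str], int]:
    """Count defect pairs by their exact strain-membership combination.

    The counts over all observed combinations partition the union, so they
    sum to the number of distinct pairs defective in at least one strain.
    """
    if not sets:
        raise ValueError("need at least one strain set")
    membership: dict[tuple[str, str], set[str]] = {}
    for strain, pairs in sets.items():
        for pair in pairs:
            membership.setdefault(pair, set()).add(strain)
    counter: Counter[frozenset[str]] = Counter(
        frozenset(strains) for strains in membership.values()
    )
    return dict(counter)


def upset_table(counts: dict[frozenset[str], int], strains: list[str]) -> pd.DataFrame:
    """Upset counts as a table: one 0/1 flag column per strain plus count."""
    rows = []
    for combo, count in counts.items():
        row = {s: int(s in combo) for s in strains}
        row["n_strains"] = len(combo)
        row["count"] = count
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["n_strains", "count"], ascending=[True, False])
        .reset_index(drop=True)
    )


def severe_strain_histogram(
    matrix: pd.DataFrame,
    retained_pairs: set[tuple[str, str]],
    severe_score: int = 3,
) -> dict[int, int]:
    """Histogram of kinases by the number of strains with a severe defect.

    A kinase is severe in a strain iff it scores ``severe_score`` in at least
    one retained condition of that strain.  Kinases severe in no strain are
    omitted, so the mapping runs over k = 1..n_strains.
    """
    sets = defect_pair_sets(matrix, retained_pairs, defect_min_score=severe_score)
    strain_count: Counter[str] = Counter()
    for strain, pairs in sets.items():
        for protein in {p for p, _ in pairs}:
            strain_count[protein] += 1
    histogram: Counter[int] = Counter(strain_count.values())
    return dict(sorted(histogram.items()))
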