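"""Condition quality control: flag globally growth-suppressing conditions.

Conditions that reduce growth of most of the array regardless of which
protein is expressed carry no kinase-specific signal.  Plotting the number
of proteins with reduced growth per condition gives a bimodal distribution;
the valley between the specific-signal mode and the globally toxic mode sets
an exclusion threshold.  The pipeline default threshold is an absolute
defect count of 175 kinases (strict ``>`` excludes), optionally replaced by
a per-pair fraction of the evaluated set or by the detected valley.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_model import condition_strains

#: Default exclusion threshold: a condition-strain pair with more than this
#: many defective kinases is considered globally toxic.
DEFAULT_MAX_DEFECT = 175


def defect_counts(
    matrix: pd.DataFrame,
    defect_min_score: int = 1,
    restrict_to: str = "kinases_only",
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count defective entities per condition-strain pair.

    ``matrix`` is the aggregated protein-level score table
    (``protein_id strain condition_id score``); entries absent from it are
    missing and excluded from numerator and denominator alike.  Under
    ``restrict_to="kinases_only"`` (the default, requiring ``annotations``)
    only non-control proteins are counted.

    Returns columns ``condition_id strain n_defect n_evaluated``.
    """
    if not 1 <= defect_min_score <= 3:
        raise ValueError("defect_min_score must be 1, 2, or 3")
    if matrix.empty:
        raise ValueError("empty score matrix")
    if restrict_to not in ("kinases_only", "all_constructs"):
        raise ValueError(f"unknown restrict_to {restrict_to!r}")
    df = matrix
    if restrict_to == "kinases_only":
        if annotations is None:
            raise ValueError("restrict_to='kinases_only' requires the annotation table")
        kinases = set(annotations.loc[~annotations["is_control"].astype(bool), "protein_id"])
        df = df[df["protein_id"].isin(kinases)]
    out = (
        df.assign(defect=df["score"] >= defect_min_score)
        .groupby(["condition_id", "strain"], sort=True)
        .agg(n_defect=("defect", "sum"), n_evaluated=("defect", "size"))
        .reset_index()
    )
    out["n_defect"] = out["n_defect"].astype(int)
    out["n_evaluated"] = out["n_evaluated"].astype(int)
    return out


def detect_valley(
    counts,
    bin_width: int = 25,
    search_range: tuple[float, float] = (100.0, 250.0),
) -> float | None:
    """Locate the density valley of a bimodal defect-count distribution.

    Histograms the counts in bins of ``bin_width`` (anchored at zero) and
    returns the midpoint of the lowest-density region whose midpoint falls
    inside ``search_range``.  A run of contiguous equally-minimal bins yields
    the centre of the run; separate runs tie-break to the lower one.  The
    valley must be interior — some histogram mass on both sides — otherwise
    the distribution is considered unimodal in range and ``None`` is
    returned with a warning.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty count sequence")
    if counts.size < 10:
        raise ValueError("need at least 10 count values to locate a valley")
    lo, hi = search_range
    edges = np.arange(0.0, counts.max() + bin_width, bin_width)
    if edges.size < 3:
        edges = np.array([0.0, bin_width, 2 * bin_width])
    hist, edges = np.histogram(counts, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0

    candidates = np.flatnonzero((mids >= lo) & (mids <= hi))
    interior = [
        i
        for i in candidates
        if hist[:i].sum() > 0 and hist[i + 1:].sum() > 0 and hist[i] < hist.max()
    ]
    if not interior:
        warnings.warn(
            "defect-count histogram is unimodal in the search range; no valley found",
            stacklevel=2,
        )
        return None
    min_density = min(hist[i] for i in interior)
    minimal = [i for i in interior if hist[i] == min_density]
    # centre of the first contiguous run of minimal bins
    run = [minimal[0]]
    for i in minimal[1:]:
        if i == run[-1] + 1:
            run.append(i)
        else:
            break
    return float((edges[run[0]] + edges[run[-1] + 1]) / 2.0)


def filter_conditions(
    counts: pd.DataFrame,
    max_defect: float = DEFAULT_MAX_DEFECT,
    max_defect_frac: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split condition-strain pairs into retained and excluded sets.

    A pair is excluded iff ``n_defect`` strictly exceeds the threshold —
    the absolute ``max_defect`` by default, or
    ``max_defect_frac * n_evaluated`` when a fraction is given instead.
    Returns ``(retained, excluded)`` DataFrames, each carrying an
    ``excluded`` flag column.
    """
    df = counts.copy()
    if max_defect_frac is not None:
        threshold = max_defect_frac * df["n_evaluated"]
    else:
        threshold = max_defect
    df["excluded"] = df["n_defect"] > threshold
    retained = df[~df["excluded"]].reset_index(drop=True)
    excluded = df[df["excluded"]].reset_index(drop=True)
    return retained, excluded


@dataclass
class EvaluableSummary:
    """Accounting of the retained condition-strain pairs."""

    n_pairs: int
    per_strain: dict[str, int]
    n_shared: int  # conditions retained in every strain of the dataset


def evaluable_accounting(
    conditions: pd.DataFrame,
    retained: pd.DataFrame,
) -> EvaluableSummary:
    """Summarise the retained pairs against the declared condition table."""
    strains = condition_strains(conditions)
    pairs = retained[["condition_id", "strain"]].drop_duplicates()
    per_strain = {s: int((pairs["strain"] == s).sum()) for s in strains}
    by_condition = pairs.groupby("condition_id")["strain"].apply(set)
    n_shared = int(sum(1 for s in by_condition if set(strains) <= s))
    return EvaluableSummary(n_pairs=len(pairs), per_strain=per_strain, n_shared=n_shared)


def retained_pair_set(retained: pd.DataFrame) -> set[tuple[str, str]]:
    """The retained (condition_id, strain) pairs as a set, for fast lookups."""
    return set(zip(retained["condition_id"], retained["strain"]))
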