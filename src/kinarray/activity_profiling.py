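"""Kinase activity profiling: condition counts, 0-4 bins, tiers, top-N.

After condition QC, each kinase is summarised per strain by the number of
retained conditions in which it caused a growth defect.  Counts are binned
0-4 (bin 0 = no phenotype; positive counts split at the quartiles of the
strain's positive-count distribution), the kinases x strains bin matrix is
hierarchically clustered (Ward linkage on Euclidean distance by default),
and the tree is cut into three activity tiers — topmost, highly, moderately
active — labelled by descending cluster mean bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

TIER_LABELS_3 = ("topmost", "highly", "moderately")


def condition_counts(
    matrix: pd.DataFrame,
    retained_pairs: set[tuple[str, str]],
    defect_min_score: int = 1,
) -> pd.DataFrame:
    """Per (protein, strain) count of retained conditions with a defect.

    Proteins present in the matrix but defect-free get explicit zero counts;
    only (condition, strain) pairs in ``retained_pairs`` contribute.
    Returns long format ``protein_id strain n_conditions``.
    """
    pair_key = list(zip(matrix["condition_id"], matrix["strain"]))
    keep = pd.Series([p in retained_pairs for p in pair_key], index=matrix.index)
    df = matrix[keep.to_numpy()]
    proteins = sorted(matrix["protein_id"].unique())
    strains = sorted({s for _, s in retained_pairs})
    counts = (
        df[df["score"] >= defect_min_score]
        .groupby(["protein_id", "strain"])
        .size()
    )
    full = pd.MultiIndex.from_product([proteins, strains], names=["protein_id", "strain"])
    out = counts.reindex(full, fill_value=0).rename("n_conditions").reset_index()
    out["n_conditions"] = out["n_conditions"].astype(int)
    return out


def bin_counts(
    counts: pd.DataFrame,
    scheme: str = "zero_plus_quartiles",
    edges: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Bin per-strain condition counts into ordinal bins 0-4.

    ``zero_plus_quartiles``: bin 0 iff count 0; positive counts split into
    bins 1-4 at the quartiles of that strain's positive-count distribution,
    with ties assigned to the lower bin so equal counts always share a bin.
    ``fixed_edges``: bin = number of edges the count reaches
    (``count >= edge``), for reproducing externally binned tables.

    Returns the input with a ``bin`` column added.
    """
    out = counts.reset_index(drop=True).copy()
    if scheme == "fixed_edges":
        if edges is None or len(edges) != 4:
            raise ValueError("fixed_edges scheme requires exactly 4 edges")
        e = np.asarray(edges, dtype=float)
        out["bin"] = (out["n_conditions"].to_numpy()[:, None] >= e).sum(axis=1)
    elif scheme == "zero_plus_quartiles":
        bins = np.zeros(len(out), dtype=int)
        for strain, idx in out.groupby("strain").groups.items():
            vals = out.loc[idx, "n_conditions"].to_numpy()
            positive = vals[vals > 0]
            if positive.size == 0:
                continue
            q = np.quantile(positive, [0.25, 0.5, 0.75])
            pos_bins = 1 + (vals[:, None] > q).sum(axis=1)
            bins[out.index.get_indexer(idx)] = np.where(vals > 0, pos_bins, 0)
        out["bin"] = bins
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    out["bin"] = out["bin"].astype(int)
    return out


def bin_matrix(binned: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format bins into a kinases x strains matrix.

    Strains with no data for a protein are imputed as bin 0 (no phenotype).
    """
    wide = binned.pivot(index="protein_id", columns="strain", values="bin")
    return wide.fillna(0).astype(int)


def cluster_tiers(
    bins: pd.DataFrame,
    k: int = 3,
    linkage: str = "ward",
    distance: str = "euclidean",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Agglomerative clustering of bin vectors into activity tiers.

    The tree is cut at ``k`` clusters and tier labels are assigned by
    descending cluster mean bin value (for k=3: topmost, highly, moderately),
    so labelling is deterministic and independent of cluster indices.  Rows
    are canonicalised (sorted by bin vector then protein id) before linkage,
    making the partition invariant to input order even with tied distances.

    Returns ``(tier table, linkage matrix)``; the tier table has columns
    ``protein_id tier cluster mean_bin`` and the scipy linkage matrix is the
    full merge record for audit.
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if bins.isna().any().any():
        bins = bins.fillna(0)
    n_distinct = bins.drop_duplicates().shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct bin vectors available"
        )
    order = bins.assign(_id=bins.index).sort_values(
        by=list(bins.columns) + ["_id"]
    ).index
    data = bins.loc[order].to_numpy(dtype=float)
    Z = scipy_linkage(data, method=linkage, metric=distance)
    clusters = fcluster(Z, t=k, criterion="maxclust")

    assignment = pd.DataFrame(
        {"protein_id": order, "cluster": clusters, "mean_row_bin": data.mean(axis=1)}
    )
    cluster_means = assignment.groupby("cluster")["mean_row_bin"].mean()
    ranked = cluster_means.sort_values(ascending=False).index
    if k == 3:
        labels = dict(zip(ranked, TIER_LABELS_3))
    else:
        labels = {c: f"tier_{i + 1}" for i, c in enumerate(ranked)}
    assignment["tier"] = assignment["cluster"].map(labels)
    assignment["mean_bin"] = assignment["cluster"].map(cluster_means)
    tiers = (
        assignment[["protein_id", "tier", "cluster", "mean_bin"]]
        .set_index("protein_id")
        .loc[bins.index]
        .rename_axis("protein_id")
        .reset_index()
    )
    return tiers, Z


def rank_top(
    bins: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    n: int = 30,
) -> pd.DataFrame:
    """Top-N kinases by activity breadth.

    Ordering key, all descending: total bin value across strains, then total
    raw condition count (when ``counts`` is given), then protein id.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    table = pd.DataFrame({"protein_id": bins.index, "bin_sum": bins.sum(axis=1).to_numpy()})
    if counts is not None:
        count_sum = counts.groupby("protein_id")["n_conditions"].sum()
        table["count_sum"] = table["protein_id"].map(count_sum).fillna(0).astype(int)
    else:
        table["count_sum"] = 0
    table = table.sort_values(
        by=["bin_sum", "count_sum", "protein_id"], ascending=False
    ).reset_index(drop=True)
    return table.head(n)
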