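"""Group comparisons of phenotype rates with a rank-sum test.

The unit of comparison is the per-condition-strain *group fraction*: for each
retained condition-strain pair, the fraction of a protein group's members
(kinases, controls, or kinase classes) whose aggregated score reaches a given
severity.  Two groups' fractions across all pairs are compared with the
Mann-Whitney/Wilcoxon rank-sum test, implemented here from first principles:
exact enumeration of the permutation null for small samples and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

GROUP_KINASE = "kinase"
GROUP_CONTROL = "control"

#: Exact enumeration is feasible within these bounds.
EXACT_MIN_N = 8
EXACT_COMBINED_N = 20


def group_fractions(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    grouping: str = "kinase_vs_control",
    severity: int = 1,
    retained_pairs: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per (condition, strain, group) fraction of members with a phenotype.

    ``grouping="kinase_vs_control"`` splits proteins by the annotation's
    ``is_control`` flag; ``grouping="ortholog_classes"`` splits non-control
    kinases into tyrosine / S-T-with-yeast-ortholog / S-T-without classes.
    The denominator is the number of group members actually evaluated
    (present in the matrix) for that condition-strain pair.
    """
    ann = annotations.set_index("protein_id")
    if grouping == "kinase_vs_control":
        group = ann["is_control"].map({False: GROUP_KINASE, True: GROUP_CONTROL})
    elif grouping == "ortholog_classes":
        is_kinase = ~ann["is_control"].astype(bool)
        tyrosine = ann["residue_class"] == "tyrosine"
        ortholog = ann["yeast_ortholog"].astype(bool)
        group = pd.Series(np.where(
            tyrosine, "tyrosine", np.where(ortholog, "st_ortholog", "st_non_ortholog")
        ), index=ann.index)
        group[~is_kinase] = np.nan
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    df = matrix.assign(group=matrix["protein_id"].map(group))
    df = df.dropna(subset=["group"])
    if retained_pairs is not None:
        keep = [
            (cond, strain) in retained_pairs
            for cond, strain in zip(df["condition_id"], df["strain"])
        ]
        df = df[np.asarray(keep)]
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("grouping yields fewer than two non-empty groups")
    out = (
        df.assign(hit=df["score"] >= severity)
        .groupby(["condition_id", "strain", "group"], sort=True)
        .agg(fraction=("hit", "mean"), n_members=("hit", "size"))
        .reset_index()
    )
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i, j): x_i > y_j} + 0.5 * #{ties}."""
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def _exact_null_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float, alternative: str) -> float:
    """Enumerate the permutation null of U over all group assignments."""
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    total = comb(n, nx)
    idx = np.arange(n)
    ge = 0
    le = 0
    eps = 1e-9
    for chosen in combinations(range(n), nx):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[idx[~mask]])
        if u >= u_obs - eps:
            ge += 1
        if u <= u_obs + eps:
            le += 1
    p_greater = ge / total
    p_less = le / total
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def rank_sum_test(
    x,
    y,
    alternative: str = "two_sided",
    method: str = "normal_approx",
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test, self-contained.

    ``U`` counts pairs with ``x_i > y_j`` (ties at half weight), so large U
    means x tends to exceed y.  ``method="exact"`` enumerates the permutation
    null whenever min(n_x, n_y) <= 8 and n_x + n_y <= 20, falling back to the
    normal approximation (with tie and continuity corrections) beyond that
    bound, with a warning.

    Returns ``(U, p_value)``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")

    u = _u_statistic(x, y)

    if method == "exact":
        if min(x.size, y.size) > EXACT_MIN_N or x.size + y.size > EXACT_COMBINED_N:
            warnings.warn(
                "sample sizes beyond the exact enumeration bound; "
                "falling back to the normal approximation",
                stacklevel=2,
            )
            method = "normal_approx"
        else:
            return u, _exact_null_pvalue(x, y, u, alternative)

    nx, ny = x.size, y.size
    n = nx + ny
    mu = nx * ny / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0  # all observations identical
    sigma = sqrt(sigma2)

    def z_of(stat_shift: float) -> float:
        return stat_shift / sigma

    if alternative == "greater":
        p = float(norm.sf(z_of(u - mu - 0.5)))
    elif alternative == "less":
        p = float(norm.cdf(z_of(u - mu + 0.5)))
    else:
        z = z_of(abs(u - mu) - 0.5) if abs(u - mu) > 0.5 else 0.0
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return u, p


def compare_groups(
    fractions: pd.DataFrame,
    pairings: list[tuple[str, str]],
    alternative: str = "two_sided",
    method: str | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Rank-sum comparisons between group phenotype-fraction distributions.

    Each comparison treats the two groups' per-condition-strain fractions as
    the two samples.  ``method=None`` picks exact enumeration when both
    samples fit the enumeration bound, the normal approximation otherwise.
    ``adjust="bh"`` appends Benjamini-Hochberg adjusted p-values (the default
    reports raw p-values only).
    """
    rows = []
    for group_a, group_b in pairings:
        xa = fractions.loc[fractions["group"] == group_a, "fraction"].to_numpy()
        xb = fractions.loc[fractions["group"] == group_b, "fraction"].to_numpy()
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"fraction table does not cover pairing ({group_a}, {group_b})")
        if method is None:
            use = (
                "exact"
                if min(xa.size, xb.size) <= EXACT_MIN_N
                and xa.size + xb.size <= EXACT_COMBINED_N
                else "normal_approx"
            )
        else:
            use = method
        u, p = rank_sum_test(xa, xb, alternative=alternative, method=use)
        rows.append(
            dict(
                group_a=group_a,
                group_b=group_b,
                n_a=xa.size,
                n_b=xb.size,
                median_a=float(np.median(xa)),
                median_b=float(np.median(xb)),
                U=u,
                p_value=p,
                method=use,
            )
        )
    report = pd.DataFrame(rows)
    if adjust == "bh":
        report["p_adjusted"] = benjamini_hochberg(report["p_value"].to_numpy())
    return report


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted
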