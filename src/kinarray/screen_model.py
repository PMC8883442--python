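"""Data model and I/O for colony-array growth screens.

The screen records ordinal growth-reduction scores (0 = none, 1 = weak,
2 = moderate, 3 = severe) for yeast spots, one spot per expression construct
x strain x growth condition x replicate.  Long-format TSV tables are the
canonical interchange form; 384-format plate grids can be read as a
convenience.  Construct-level spots are aggregated to one value per protein
(kinase or control) per strain per condition before any downstream analysis.

Tables are held as :class:`pandas.DataFrame` with fixed column schemas:

``scores``
    ``protein_id construct_id vector strain condition_id replicate score``
``constructs``
    ``construct_id protein_id orf_clone vector is_control is_kinase_dead``
``conditions``
    ``condition_id treatment additive concentration unit temperature``
    plus one ``evaluated_<strain>`` 0/1 flag column per strain
``annotations``
    ``protein_id family_group residue_class yeast_ortholog is_control
    is_kinase_dead is_dark is_cancer``
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "protein_id",
    "construct_id",
    "vector",
    "strain",
    "condition_id",
    "replicate",
    "score",
]

CONSTRUCT_COLUMNS = [
    "construct_id",
    "protein_id",
    "orf_clone",
    "vector",
    "is_control",
    "is_kinase_dead",
]

ANNOTATION_COLUMNS = [
    "protein_id",
    "family_group",
    "residue_class",
    "yeast_ortholog",
    "is_control",
    "is_kinase_dead",
    "is_dark",
    "is_cancer",
]

CONDITION_BASE_COLUMNS = [
    "condition_id",
    "treatment",
    "additive",
    "concentration",
    "unit",
    "temperature",
]

#: Valid ordinal growth-reduction scores.
SCORE_RANGE = (0, 3)

#: Row letters of a 384-format plate (16 rows x 24 columns).
PLATE_384_ROWS = tuple(string.ascii_uppercase[:16])


class SchemaError(ValueError):
    """A required column is missing or the table layout is wrong."""


class ValidationError(ValueError):
    """Row-level content violates the data contract."""


class IntegrityError(ValueError):
    """Cross-table references are inconsistent."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Long-format score tables
# ---------------------------------------------------------------------------

def read_screen_long(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format spot-score table.

    Parameters
    ----------
    path
        TSV (or CSV) file with one row per scored spot.
    schema
        Optional mapping from canonical column names (see
        :data:`SCORE_COLUMNS`) to the column names used in the file, for
        tables produced outside this package.
    sep
        Field separator; autodetected from the extension when omitted
        (``.csv`` -> comma, otherwise tab).

    Returns
    -------
    pandas.DataFrame
        Columns :data:`SCORE_COLUMNS`, ``score`` coerced to integers in 0-3.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If any score is missing, non-integer, or outside 0-3; offending
        row indices are listed in the message.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("score table %s is empty; returning no observations", path)
        return pd.DataFrame(columns=SCORE_COLUMNS)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    required = ["construct_id", "strain", "condition_id", "replicate", "score"]
    _require_columns(df, required, f"score table {path}")
    for optional in ("protein_id", "vector"):
        if optional not in df.columns:
            df[optional] = ""
    if df.empty:
        logger.warning("score table %s has a header but no rows", path)
        return pd.DataFrame(columns=SCORE_COLUMNS)

    score = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[score.isna() | (score != score.round())].tolist()
    if bad:
        raise ValidationError(f"non-integer score in rows {bad} of {path}")
    score = score.astype(int)
    out_of_range = df.index[(score < SCORE_RANGE[0]) | (score > SCORE_RANGE[1])].tolist()
    if out_of_range:
        raise ValidationError(
            f"score outside {SCORE_RANGE[0]}-{SCORE_RANGE[1]} in rows "
            f"{out_of_range} of {path}"
        )
    df = df.assign(score=score, replicate=pd.to_numeric(df["replicate"]).astype(int))
    return df[SCORE_COLUMNS].reset_index(drop=True)


def write_screen_long(observations: pd.DataFrame, path: str | Path) -> None:
    """Write observations as the canonical tab-separated long table."""
    _require_columns(observations, SCORE_COLUMNS, "score table")
    observations[SCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_plate_grid(
    path: str | Path,
    layout: Mapping[tuple[str, int], str],
    strain: str,
    condition_id: str,
    replicate: int = 1,
    n_rows: int = 16,
    n_cols: int = 24,
) -> pd.DataFrame:
    """Read a plate grid file into spot observations.

    The grid is a TSV whose header row holds 1-based column numbers and whose
    first column holds row letters (A-P for the default 384 format).  Cell
    values are scores 0-3; blank cells are *missing* observations, never
    score 0.  ``layout`` maps (row letter, column number) to the construct
    gridded at that position; positions absent from the layout are skipped
    with a warning.

    Returns a DataFrame with columns
    ``construct_id strain condition_id replicate score``.
    """
    grid = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    grid.index = grid.index.astype(str).str.strip()
    grid.columns = [int(c) for c in grid.columns]
    if grid.shape != (n_rows, n_cols):
        raise SchemaError(
            f"grid {path} has shape {grid.shape}, expected ({n_rows}, {n_cols}); "
            "pass n_rows/n_cols for other plate formats"
        )
    records = []
    skipped = 0
    for row_letter in grid.index:
        for col in grid.columns:
            raw = grid.at[row_letter, col]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            raw = str(raw).strip()
            if raw == "" or raw.lower() == "nan":
                continue
            key = (row_letter, int(col))
            if key not in layout:
                skipped += 1
                continue
            score = int(raw)
            if score < SCORE_RANGE[0] or score > SCORE_RANGE[1]:
                raise ValidationError(f"score {score} at {row_letter}{col} of {path}")
            records.append((layout[key], strain, condition_id, replicate, score))
    if skipped:
        logger.warning(
            "%d scored positions in %s absent from the layout were ignored", skipped, path
        )
    return pd.DataFrame(
        records, columns=["construct_id", "strain", "condition_id", "replicate", "score"]
    )


# ---------------------------------------------------------------------------
# Side tables
# ---------------------------------------------------------------------------

def read_constructs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CONSTRUCT_COLUMNS, f"construct table {path}")
    for c in ("is_control", "is_kinase_dead"):
        df[c] = df[c].astype(int).astype(bool)
    return df[CONSTRUCT_COLUMNS]


def write_constructs(constructs: pd.DataFrame, path: str | Path) -> None:
    out = constructs[CONSTRUCT_COLUMNS].copy()
    for c in ("is_control", "is_kinase_dead"):
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ANNOTATION_COLUMNS, f"annotation table {path}")
    for c in ("yeast_ortholog", "is_control", "is_kinase_dead", "is_dark", "is_cancer"):
        df[c] = df[c].astype(int).astype(bool)
    return df[ANNOTATION_COLUMNS]


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    out = annotations[ANNOTATION_COLUMNS].copy()
    for c in ("yeast_ortholog", "is_control", "is_kinase_dead", "is_dark", "is_cancer"):
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_conditions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CONDITION_BASE_COLUMNS, f"condition table {path}")
    for c in condition_strains(df):
        df[f"evaluated_{c}"] = df[f"evaluated_{c}"].astype(int)
    return df


def write_conditions(conditions: pd.DataFrame, path: str | Path) -> None:
    conditions.to_csv(path, sep="\t", index=False)


def condition_strains(conditions: pd.DataFrame) -> list[str]:
    """Strains declared by the ``evaluated_<strain>`` flag columns."""
    return [c[len("evaluated_"):] for c in conditions.columns if c.startswith("evaluated_")]


def evaluated_in(conditions: pd.DataFrame) -> dict[str, set[str]]:
    """Map condition_id -> set of strains the condition was evaluated in."""
    strains = condition_strains(conditions)
    out: dict[str, set[str]] = {}
    for _, row in conditions.iterrows():
        out[row["condition_id"]] = {s for s in strains if int(row[f"evaluated_{s}"]) == 1}
    return out


# ---------------------------------------------------------------------------
# Clone-to-protein aggregation
# ---------------------------------------------------------------------------

def aggregate_to_kinase(
    observations: pd.DataFrame,
    constructs: pd.DataFrame,
    rule: str = "max",
) -> pd.DataFrame:
    """Aggregate spot scores over clones, vectors, and replicates.

    One value per (protein, strain, condition) is produced.  Under
    ``rule="max"`` any active construct is taken as evidence of activity, so
    the aggregate is the maximum spot score; ``rule="median"`` uses the lower
    median of the contributing scores (rounded down to stay on the ordinal
    scale).  Kinase-dead and control constructs carry their own ``protein_id``
    in the construct table and therefore never pool with the wild-type kinase.

    Returns a DataFrame with columns ``protein_id strain condition_id score``.
    """
    if rule not in ("max", "median"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    mapping = constructs.set_index("construct_id")["protein_id"]
    unknown = set(observations["construct_id"]) - set(mapping.index)
    if unknown:
        raise IntegrityError(f"observations reference undeclared constructs: {sorted(unknown)}")
    protein = observations["construct_id"].map(mapping)
    df = observations.assign(protein_id=protein)
    grouped = df.groupby(["protein_id", "strain", "condition_id"], sort=True)["score"]
    if rule == "max":
        agg = grouped.max()
    else:
        agg = grouped.median().apply(np.floor).astype(int)
    out = agg.reset_index()
    out["score"] = out["score"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only consistency check of a screen dataset."""

    issues: list[str] = field(default_factory=list)
    per_strain_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    observations: pd.DataFrame,
    constructs: pd.DataFrame,
    conditions: pd.DataFrame,
    annotations: pd.DataFrame,
) -> ValidationReport:
    """Check referential integrity of a dataset; never raises.

    Reported issues: orphan construct / condition / protein references,
    duplicate primary keys in any table, and scores recorded for a strain in
    which the condition was not evaluated.
    """
    report = ValidationReport()

    dup_obs = observations.duplicated(
        subset=["construct_id", "strain", "condition_id", "replicate"]
    )
    for idx in observations.index[dup_obs]:
        row = observations.loc[idx]
        report.issues.append(
            "duplicate observation key "
            f"({row['construct_id']}, {row['strain']}, {row['condition_id']}, {row['replicate']})"
        )
    for table, key, name in (
        (constructs, "construct_id", "construct"),
        (conditions, "condition_id", "condition"),
        (annotations, "protein_id", "annotation"),
    ):
        for value in table.loc[table.duplicated(subset=[key]), key]:
            report.issues.append(f"duplicate {name} key {value}")

    known_constructs = set(constructs["construct_id"])
    for value in sorted(set(observations["construct_id"]) - known_constructs):
        report.issues.append(f"orphan construct reference {value}")
    known_conditions = set(conditions["condition_id"])
    for value in sorted(set(observations["condition_id"]) - known_conditions):
        report.issues.append(f"orphan condition reference {value}")
    known_proteins = set(annotations["protein_id"])
    for value in sorted(set(constructs["protein_id"]) - known_proteins):
        report.issues.append(f"construct protein {value} absent from annotations")

    evaluated = evaluated_in(conditions)
    seen_pairs = observations[["condition_id", "strain"]].drop_duplicates()
    for _, row in seen_pairs.iterrows():
        cond, strain = row["condition_id"], row["strain"]
        if cond in evaluated and strain not in evaluated[cond]:
            report.issues.append(
                f"scores recorded for condition {cond} in strain {strain}, "
                "which is not flagged as evaluated"
            )

    report.per_strain_counts = observations.groupby("strain").size().to_dict()
    return report
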