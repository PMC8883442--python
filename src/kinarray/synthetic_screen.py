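"""Synthetic screen, phospho-Y2H plate, and growth-curve generators.

Every downstream stage of the pipeline can be exercised on data with known
planted truth.  The colony-score generator uses a cumulative-logit ordinal
model: each spot for protein k, strain s, condition c draws a latent
logistic variable L and records

    score = #{ j in {1,2,3} : a*activity_k + b*severity_c + gamma_s
                              + d_class(k) + L > theta_j }

so ``P(score >= j) = sigmoid(eta - theta_j)`` with strictly increasing
thresholds theta.  Controls and kinase-dead constructs have activity 0; a
minority of conditions carry a much larger severity ("globally toxic") which
the condition-QC stage is expected to flag.

The default configuration mirrors the reference screen's scale: 266 kinases
(41 tyrosine, 179 S/T with a yeast ortholog, 46 S/T without), 80 controls
(70 unrelated proteins + 10 kinase-dead variants), four strains, 73
conditions of which ~17% are toxic, two clones per protein and two replicate
spots, giving roughly 350,000 scored spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth_kinetics import GrowthCurve

CLASS_TYROSINE = "tyrosine"
CLASS_ST_ORTHOLOG = "st_ortholog"
CLASS_ST_NON_ORTHOLOG = "st_non_ortholog"

TIER_NAMES = ("inactive", "moderate", "high", "topmost")


class ConfigurationError(ValueError):
    """The simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic colony screen.

    Counts follow the reference array; the ordinal-model coefficients are
    artifact parameters chosen so that active kinases produce defects in a
    realistic fraction of conditions while toxic conditions suppress growth
    of nearly every construct.
    """

    n_tyrosine: int = 41
    n_st_ortholog: int = 179
    n_st_non_ortholog: int = 46
    n_controls: int = 70
    n_kinase_dead: int = 10
    strains: tuple[str, ...] = ("BY4742", "L40c", "W303", "Y258")
    strain_offsets: tuple[float, ...] = (0.0, 0.3, -0.2, 0.5)
    strain_eval_prob: tuple[float, ...] = (1.0, 0.95, 0.95, 0.85)
    n_conditions: int = 73
    fraction_toxic: float = 0.17
    severity_mean: float = 0.0
    severity_sd: float = 0.4
    toxic_severity_mean: float = 8.0
    tier_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    activity_levels: tuple[float, ...] = (0.0, 0.5, 2.0, 3.0)
    activity_coef: float = 1.6
    severity_coef: float = 1.0
    class_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            CLASS_TYROSINE: 1.0,
            CLASS_ST_ORTHOLOG: 0.5,
            CLASS_ST_NON_ORTHOLOG: 0.0,
        }
    )
    thresholds: tuple[float, float, float] = (5.5, 6.5, 7.5)
    clones_per_protein: int = 2
    replicates: int = 2
    dark_fraction: float = 0.27
    cancer_fraction: float = 0.63
    seed: int = 0

    @property
    def n_kinases(self) -> int:
        return self.n_tyrosine + self.n_st_ortholog + self.n_st_non_ortholog

    def validate(self) -> None:
        if min(
            self.n_tyrosine,
            self.n_st_ortholog,
            self.n_st_non_ortholog,
            self.n_controls,
            self.n_kinase_dead,
            self.n_conditions,
        ) < 0:
            raise ConfigurationError("all counts must be >= 0")
        if self.n_kinases == 0:
            raise ConfigurationError("at least one kinase is required")
        if not (len(self.strains) == len(self.strain_offsets) == len(self.strain_eval_prob)):
            raise ConfigurationError("strains, offsets, and evaluation probabilities must align")
        if not 0.0 <= self.fraction_toxic <= 1.0:
            raise ConfigurationError("fraction_toxic must lie in [0, 1]")
        if len(self.tier_proportions) != 4 or not math.isclose(
            sum(self.tier_proportions), 1.0, abs_tol=1e-9
        ):
            raise ConfigurationError("tier_proportions must be a 4-simplex")
        if any(p < 0 for p in self.tier_proportions):
            raise ConfigurationError("tier_proportions must be non-negative")
        if len(self.activity_levels) != len(self.tier_proportions):
            raise ConfigurationError("activity_levels must match tier_proportions in length")
        t1, t2, t3 = self.thresholds
        if not t1 < t2 < t3:
            raise ConfigurationError("thresholds must be strictly increasing")
        if self.clones_per_protein < 1 or self.replicates < 1:
            raise ConfigurationError("clones_per_protein and replicates must be >= 1")
        if self.n_kinase_dead > self.n_kinases:
            raise ConfigurationError("cannot derive more kinase-dead variants than kinases")


@dataclass
class PlantedTruth:
    """Latent state used to generate a dataset, kept for recovery checks."""

    protein_tier: dict[str, int]
    protein_class: dict[str, str]
    condition_toxic: dict[str, bool]
    condition_severity: dict[str, float]
    strain_offsets: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenDataset:
    """The four interchange tables of a colony screen."""

    scores: pd.DataFrame
    constructs: pd.DataFrame
    conditions: pd.DataFrame
    annotations: pd.DataFrame


def _exact_tier_assignment(n: int, proportions: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Assign tiers 0-3 with counts as close to n*proportions as possible."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    tiers = np.repeat(np.arange(len(proportions)), counts)
    return rng.permutation(tiers)


def simulate_screen(config: SimConfig | None = None) -> tuple[ScreenDataset, PlantedTruth]:
    """Generate a full synthetic colony screen with planted truth.

    Deterministic given ``config.seed``.  Returns the four interchange tables
    (long score table, constructs, conditions, annotations) plus the planted
    latent state.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- proteins and annotations ------------------------------------------
    classes = (
        [CLASS_TYROSINE] * config.n_tyrosine
        + [CLASS_ST_ORTHOLOG] * config.n_st_ortholog
        + [CLASS_ST_NON_ORTHOLOG] * config.n_st_non_ortholog
    )
    kinase_ids = [f"KIN{i + 1:04d}" for i in range(config.n_kinases)]
    # tiers are assigned stratified within class, so class comparisons are
    # not confounded by unequal tier composition
    tiers = np.empty(config.n_kinases, dtype=int)
    offset = 0
    for n_class in (config.n_tyrosine, config.n_st_ortholog, config.n_st_non_ortholog):
        tiers[offset : offset + n_class] = _exact_tier_assignment(
            n_class, config.tier_proportions, rng
        )
        offset += n_class

    control_ids = [f"CTRL{i + 1:03d}" for i in range(config.n_controls)]
    kd_parents = kinase_ids[: config.n_kinase_dead]
    kd_ids = [f"{k}-KD" for k in kd_parents]

    ann_rows = []
    for pid, cls, tier in zip(kinase_ids, classes, tiers):
        ann_rows.append(
            dict(
                protein_id=pid,
                family_group=cls,
                residue_class="tyrosine" if cls == CLASS_TYROSINE else "serine_threonine",
                yeast_ortholog=cls == CLASS_ST_ORTHOLOG,
                is_control=False,
                is_kinase_dead=False,
                is_dark=False,
                is_cancer=False,
            )
        )
    for pid in control_ids:
        ann_rows.append(
            dict(
                protein_id=pid,
                family_group="control",
                residue_class="",
                yeast_ortholog=False,
                is_control=True,
                is_kinase_dead=False,
                is_dark=False,
                is_cancer=False,
            )
        )
    for pid, parent_cls in zip(kd_ids, classes[: config.n_kinase_dead]):
        ann_rows.append(
            dict(
                protein_id=pid,
                family_group=parent_cls,
                residue_class="tyrosine" if parent_cls == CLASS_TYROSINE else "serine_threonine",
                yeast_ortholog=parent_cls == CLASS_ST_ORTHOLOG,
                is_control=True,
                is_kinase_dead=True,
                is_dark=False,
                is_cancer=False,
            )
        )
    annotations = pd.DataFrame(ann_rows)
    n_kin = config.n_kinases
    dark_idx = rng.choice(n_kin, size=int(round(config.dark_fraction * n_kin)), replace=False)
    cancer_idx = rng.choice(n_kin, size=int(round(config.cancer_fraction * n_kin)), replace=False)
    annotations.loc[dark_idx, "is_dark"] = True
    annotations.loc[cancer_idx, "is_cancer"] = True

    # --- constructs ---------------------------------------------------------
    protein_ids = kinase_ids + control_ids + kd_ids
    levels = np.asarray(config.activity_levels, dtype=float)
    activity = np.concatenate(
        [levels[tiers], np.zeros(len(control_ids) + len(kd_ids))]
    )
    class_offset = np.array(
        [config.class_offsets.get(cls, 0.0) for cls in classes]
        + [0.0] * len(control_ids)
        + [config.class_offsets.get(cls, 0.0) for cls in classes[: config.n_kinase_dead]]
    )
    con_rows = []
    for pid in protein_ids:
        for clone in range(config.clones_per_protein):
            con_rows.append(
                dict(
                    construct_id=f"{pid}_c{clone + 1}",
                    protein_id=pid,
                    orf_clone=f"orf_{pid}_{clone + 1}",
                    vector="nls" if clone % 2 else "no_nls",
                    is_control=pid in set(control_ids) or pid in set(kd_ids),
                    is_kinase_dead=pid in set(kd_ids),
                )
            )
    constructs = pd.DataFrame(con_rows)

    # --- conditions ---------------------------------------------------------
    condition_ids = [f"COND{i + 1:03d}" for i in range(config.n_conditions)]
    n_toxic = int(round(config.fraction_toxic * config.n_conditions))
    toxic = np.zeros(config.n_conditions, dtype=bool)
    toxic[rng.choice(config.n_conditions, size=n_toxic, replace=False)] = True
    severity = rng.normal(config.severity_mean, config.severity_sd, config.n_conditions)
    severity[toxic] = rng.normal(
        config.toxic_severity_mean, config.severity_sd, int(toxic.sum())
    )
    evaluated = np.ones((config.n_conditions, len(config.strains)), dtype=int)
    for j, prob in enumerate(config.strain_eval_prob):
        evaluated[:, j] = rng.random(config.n_conditions) < prob
    # every condition is evaluated in at least one strain
    none_evaluated = evaluated.sum(axis=1) == 0
    evaluated[none_evaluated, 0] = 1

    cond = pd.DataFrame(
        dict(
            condition_id=condition_ids,
            treatment=[f"treatment_{(i % 33) + 1}" for i in range(config.n_conditions)],
            additive=["" for _ in condition_ids],
            concentration=np.round(rng.uniform(0.1, 10.0, config.n_conditions), 2),
            unit=["mM" for _ in condition_ids],
            temperature=[30.0 for _ in condition_ids],
        )
    )
    for j, strain in enumerate(config.strains):
        cond[f"evaluated_{strain}"] = evaluated[:, j]

    # --- spot scores (vectorised over the full factorial) -------------------
    n_constructs = len(constructs)
    construct_protein_idx = np.repeat(np.arange(len(protein_ids)), config.clones_per_protein)
    eta_protein = config.activity_coef * activity + class_offset  # per protein

    strain_arrays, frames = np.asarray(config.strain_offsets), []
    for j, strain in enumerate(config.strains):
        cond_mask = evaluated[:, j].astype(bool)
        cond_idx = np.flatnonzero(cond_mask)
        n_c = cond_idx.size
        if n_c == 0:
            continue
        # eta for every (construct, condition) in this strain
        eta = (
            eta_protein[construct_protein_idx][:, None]
            + config.severity_coef * severity[cond_idx][None, :]
            + strain_arrays[j]
        )
        shape = (n_constructs, n_c, config.replicates)
        latent = rng.logistic(0.0, 1.0, size=shape)
        z = eta[:, :, None] + latent
        t1, t2, t3 = config.thresholds
        score = (z > t1).astype(np.int8) + (z > t2) + (z > t3)
        frames.append(
            pd.DataFrame(
                dict(
                    protein_id=np.repeat(
                        constructs["protein_id"].to_numpy(), n_c * config.replicates
                    ),
                    construct_id=np.repeat(
                        constructs["construct_id"].to_numpy(), n_c * config.replicates
                    ),
                    vector=np.repeat(constructs["vector"].to_numpy(), n_c * config.replicates),
                    strain=strain,
                    condition_id=np.tile(
                        np.repeat(np.asarray(condition_ids)[cond_idx], config.replicates),
                        n_constructs,
                    ),
                    replicate=np.tile(
                        np.arange(1, config.replicates + 1), n_constructs * n_c
                    ),
                    score=score.reshape(-1),
                )
            )
        )
    scores = pd.concat(frames, ignore_index=True)
    scores["score"] = scores["score"].astype(int)

    truth = PlantedTruth(
        protein_tier={pid: int(t) for pid, t in zip(kinase_ids, tiers)},
        protein_class=dict(zip(kinase_ids, classes)),
        condition_toxic=dict(zip(condition_ids, toxic.tolist())),
        condition_severity=dict(zip(condition_ids, severity.tolist())),
        strain_offsets=dict(zip(config.strains, config.strain_offsets)),
    )
    return ScreenDataset(scores, constructs, cond, annotations), truth


# ---------------------------------------------------------------------------
# Phospho-Y2H plates
# ---------------------------------------------------------------------------

Y2H_COLUMNS = [
    "bait",
    "prey",
    "kinase",
    "construct_type",
    "media",
    "cu_um",
    "dilution_step",
    "replicate",
    "growth",
]

_VALID_MODES = ("loss", "gain")


def simulate_y2h_plate(
    n_kinases: int = 100,
    true_modulators: Mapping[str, str | tuple[str, bool]] | None = None,
    baseline_interaction: bool = True,
    dilutions: int = 3,
    replicates: int = 3,
    noise: float = 0.5,
    seed: int = 0,
    shift: int = 3,
    n_controls: int = 8,
    toxic_kinases: Sequence[str] = (),
    bait: str = "BAIT",
    prey: str = "PREY",
    cu_um: float = 20.0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a three-replicate phospho-Y2H interaction-mating plate.

    One diploid per array kinase carries bait, prey, and the kinase.  SD3
    growth (viability control) is always at full dilution depth unless the
    kinase is growth-toxic.  SD5 growth (interaction readout) starts from a
    baseline dilution score — full depth when the bait-prey pair interacts
    without a kinase, zero otherwise — and true modulators shift that score
    down (loss of interaction) or up (gain) by ``shift`` steps.  Gaussian
    jitter with SD ``noise`` is added to the target dilution score per
    replicate, then discretised and clipped to the valid range.

    ``true_modulators`` maps kinase id -> mode ("loss"/"gain") or
    (mode, phospho_dependent).  Phospho-dependent modulators get a matching
    kinase-dead partner row set *without* the shift; non-phospho-dependent
    ones (scaffold/ternary-complex effects) shift with the kinase-dead
    partner too.

    Returns (long observation table, planted truth).  The truth reuses the
    screen's container: ``protein_tier`` holds 1 for modulators, and
    ``protein_class`` the planted mode; ``condition_toxic`` records the
    phospho-dependence flag per modulator.
    """
    if dilutions < 2:
        raise ConfigurationError("dilutions must be >= 2")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    true_modulators = dict(true_modulators or {})
    modes: dict[str, str] = {}
    phospho_dep: dict[str, bool] = {}
    for kinase, spec in true_modulators.items():
        if isinstance(spec, tuple):
            mode, dep = spec
        else:
            mode, dep = spec, True
        if mode not in _VALID_MODES:
            raise ConfigurationError(f"unknown modulation mode {mode!r} for {kinase}")
        modes[kinase] = mode
        phospho_dep[kinase] = bool(dep)

    rng = np.random.default_rng(seed)
    kinase_ids = [f"KIN{i + 1:04d}" for i in range(n_kinases)]
    unknown = set(modes) - set(kinase_ids) - set(toxic_kinases)
    if unknown:
        raise ConfigurationError(f"true modulators not on the plate: {sorted(unknown)}")

    max_score = dilutions  # dilution_score ranges 0..dilutions
    sd5_base = max_score if baseline_interaction else 0
    toxic = set(toxic_kinases)

    rows: list[tuple] = []

    def emit(kinase: str, construct_type: str, shifted: bool) -> None:
        sd3_target = 0 if kinase in toxic else max_score
        sd5_target = sd5_base
        if shifted:
            delta = -shift if modes[kinase] == "loss" else shift
            sd5_target = int(np.clip(sd5_base + delta, 0, max_score))
        if kinase in toxic:
            sd5_target = 0
        for media, target in (("SD3", sd3_target), ("SD5", sd5_target)):
            jitter = rng.normal(0.0, noise, replicates) if noise > 0 else np.zeros(replicates)
            rep_scores = np.clip(np.rint(target + jitter), 0, max_score).astype(int)
            for rep in range(1, replicates + 1):
                depth = rep_scores[rep - 1]
                for step in range(dilutions):
                    growth = int(np.clip(depth - step, 0, 3))
                    rows.append(
                        (bait, prey, kinase, construct_type, media, cu_um, step, rep, growth)
                    )

    control_ids = [f"YCTRL{i + 1:02d}" for i in range(n_controls)]
    for kinase in control_ids:
        emit(kinase, "control", shifted=False)
    for kinase in kinase_ids:
        emit(kinase, "wt", shifted=kinase in modes)
        if kinase in modes:
            emit(kinase, "kinase_dead", shifted=not phospho_dep[kinase])

    plate = pd.DataFrame(rows, columns=Y2H_COLUMNS)
    truth = PlantedTruth(
        protein_tier={k: 1 for k in modes},
        protein_class=dict(modes),
        condition_toxic=dict(phospho_dep),
        condition_severity={},
        strain_offsets={},
    )
    return plate, truth


# ---------------------------------------------------------------------------
# Liquid growth curves
# ---------------------------------------------------------------------------

def default_time_grid() -> np.ndarray:
    """24 h sampled every 10 min, the plate reader's acquisition grid."""
    return np.arange(0.0, 24.0 + 1e-9, 1.0 / 6.0)


def simulate_growth_curve(
    K: float,
    r: float,
    t0: float,
    baseline: float,
    noise_sd: float = 0.0,
    t_grid: np.ndarray | None = None,
    seed: int = 0,
    sample: str = "sample",
    condition: str = "standard",
    replicate: int = 1,
) -> GrowthCurve:
    """Simulate a logistic OD595 time series.

    ``OD(t) = baseline + (K - baseline) / (1 + exp(-r (t - t0))) + eps`` with
    ``eps ~ Normal(0, noise_sd)``.  ``K`` is the carrying capacity (OD),
    ``r`` the growth rate per hour, ``t0`` the inflection time in hours.
    """
    if r <= 0:
        raise ConfigurationError("growth rate r must be positive")
    if not K > baseline >= 0:
        raise ConfigurationError("require K > baseline >= 0")
    t = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    od = baseline + (K - baseline) / (1.0 + np.exp(-r * (t - t0)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, t.size)
    od = np.clip(od, 0.0, None)
    return GrowthCurve(sample=sample, condition=condition, replicate=replicate, times=t, od=od)
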