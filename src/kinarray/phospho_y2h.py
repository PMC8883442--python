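"""Phospho-Y2H modulation calling.

A bait-prey pair is co-expressed with one array kinase per diploid; growth on
selective media (SD5) reports the interaction while permissive media (SD3)
reports viability.  Growth strength is quantified ordinally as a *dilution
score*: one plus the deepest 1:10 dilution step still growing.  A kinase is
called a *loss* modulator when its SD5 dilution score drops at least
``min_shift`` steps below the plate baseline in enough replicates while SD3
stays near baseline (growth-toxic kinases — the screen's central confound —
are gated out by the SD3 viability check), and a *gain* modulator by the
mirrored rule on a non-interacting baseline.  Pairing each wild-type call
with its kinase-dead partner distinguishes phosphorylation-dependent
modulation from scaffold or ternary-complex effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_model import IntegrityError

MODE_LOSS = "loss"
MODE_GAIN = "gain"
MODE_NONE = "none"


def dilution_score(series) -> int:
    """Ordinal growth strength of one dilution series.

    ``series`` maps dilution step (0 = undiluted) to growth 0-3.  The score
    is one plus the deepest step with growth >= 1, or 0 when nothing grows;
    missing steps are skipped.  Growth reappearing after an empty step is
    scored literally but triggers a data-quality warning.
    """
    if isinstance(series, pd.Series):
        items = list(series.items())
    else:
        items = list(dict(series).items())
    if not items:
        raise ValueError("empty dilution series")
    items.sort(key=lambda kv: kv[0])
    growing = [step for step, growth in items if growth >= 1]
    if not growing:
        return 0
    deepest = growing[-1]
    holes = [step for step, growth in items if step < deepest and growth < 1]
    if holes:
        warnings.warn(
            f"non-monotone dilution series: no growth at step(s) {holes} "
            f"but growth at step {deepest}",
            stacklevel=2,
        )
    return 1 + deepest


def replicate_scores(plate: pd.DataFrame) -> pd.DataFrame:
    """Collapse dilution series to one score per kinase/media/replicate.

    Returns columns ``kinase construct_type media replicate score``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-series monotonicity warnings
        scores = (
            plate.groupby(["kinase", "construct_type", "media", "replicate"], sort=True)
            .apply(
                lambda g: dilution_score(dict(zip(g["dilution_step"], g["growth"]))),
                include_groups=False,
            )
            .rename("score")
            .reset_index()
        )
    return scores


def baseline_estimate(
    plate: pd.DataFrame,
    strategy: str = "control_kinases",
) -> dict[str, float]:
    """Per-media baseline dilution score of the plate.

    ``control_kinases`` uses the annotated non-related control kinases
    (``construct_type == "control"``), pooling replicates by median per
    kinase and taking the median across kinases; with no controls present it
    falls back to ``plate_median`` with a warning.
    """
    if strategy not in ("control_kinases", "plate_median"):
        raise ValueError(f"unknown baseline strategy {strategy!r}")
    scores = replicate_scores(plate)
    if strategy == "control_kinases":
        controls = scores[scores["construct_type"] == "control"]
        if controls.empty:
            warnings.warn(
                "no control kinases on the plate; falling back to plate median",
                stacklevel=2,
            )
            controls = scores
    else:
        controls = scores
    per_kinase = controls.groupby(["media", "kinase"])["score"].median()
    return per_kinase.groupby("media").median().to_dict()


@dataclass
class Y2HCall:
    """Modulation verdict for one kinase construct."""

    kinase: str
    construct_type: str
    mode: str
    effect_size: int
    viability_ok: bool
    replicate_support: float
    toxic: bool = False
    phospho_dependent: bool | None = None


def call_modulators(
    plate: pd.DataFrame,
    baseline: dict[str, float] | None = None,
    min_shift: float = 2,
    replicate_rule: float = 2 / 3,
    viability_max_drop: int = 1,
    baseline_strategy: str = "control_kinases",
) -> pd.DataFrame:
    """Call loss/gain interaction modulators from a phospho-Y2H plate.

    A loss call requires the SD5 dilution score to sit at least ``min_shift``
    steps below the SD5 baseline in at least ``replicate_rule`` of the
    replicates, with the SD3 score within ``viability_max_drop`` of the SD3
    baseline (otherwise the kinase is growth-toxic and reported with mode
    ``none`` and a toxicity flag).  A gain call is the mirrored rule.  Loss
    and gain are mutually exclusive for a given baseline.

    Control constructs are never called.  Returns one row per (kinase,
    construct_type) with the :class:`Y2HCall` fields.
    """
    if baseline is None:
        baseline = baseline_estimate(plate, strategy=baseline_strategy)
    if not {"SD3", "SD5"} <= set(baseline):
        raise ValueError("baseline must cover both SD3 and SD5 media")
    base3, base5 = baseline["SD3"], baseline["SD5"]

    scores = replicate_scores(plate)
    calls: list[Y2HCall] = []
    for (kinase, ctype), grp in scores.groupby(["kinase", "construct_type"], sort=True):
        if ctype == "control":
            continue
        sd5 = grp.loc[grp["media"] == "SD5"].sort_values("replicate")["score"].to_numpy()
        sd3 = grp.loc[grp["media"] == "SD3"].sort_values("replicate")["score"].to_numpy()
        n_rep = max(len(sd5), 1)
        viable = bool(np.median(sd3) >= base3 - viability_max_drop) if sd3.size else False

        if math.isfinite(min_shift):
            loss_hits = int((sd5 <= base5 - min_shift).sum())
            gain_hits = int((sd5 >= base5 + min_shift).sum())
        else:
            loss_hits = gain_hits = 0
        loss_support = loss_hits / n_rep
        gain_support = gain_hits / n_rep

        mode = MODE_NONE
        support = 0.0
        effect = 0
        if viable:
            loss_ok = loss_support >= replicate_rule and sd5.size > 0
            gain_ok = gain_support >= replicate_rule and sd5.size > 0
            if loss_ok and not gain_ok:
                mode, support = MODE_LOSS, loss_support
                effect = int(round(base5 - float(np.median(sd5))))
            elif gain_ok and not loss_ok:
                mode, support = MODE_GAIN, gain_support
                effect = int(round(float(np.median(sd5)) - base5))
        calls.append(
            Y2HCall(
                kinase=kinase,
                construct_type=ctype,
                mode=mode,
                effect_size=effect,
                viability_ok=viable,
                replicate_support=support,
                toxic=not viable,
            )
        )
    return pd.DataFrame([c.__dict__ for c in calls])


def phospho_dependence(wt_call, kd_call) -> bool:
    """Whether a modulation requires catalytic activity.

    True iff the wild-type kinase modulates (mode != none) and its
    kinase-dead partner does not.  A kinase-dead construct reproducing the
    wild-type mode indicates a scaffold or ternary-complex effect, not
    phosphorylation.
    """
    wt_kinase = wt_call["kinase"] if isinstance(wt_call, (dict, pd.Series)) else wt_call.kinase
    kd_kinase = kd_call["kinase"] if isinstance(kd_call, (dict, pd.Series)) else kd_call.kinase
    if wt_kinase != kd_kinase:
        raise IntegrityError(
            f"wild-type call is for {wt_kinase} but kinase-dead call is for {kd_kinase}"
        )
    wt_mode = wt_call["mode"] if isinstance(wt_call, (dict, pd.Series)) else wt_call.mode
    kd_mode = kd_call["mode"] if isinstance(kd_call, (dict, pd.Series)) else kd_call.mode
    return wt_mode != MODE_NONE and kd_mode == MODE_NONE


def annotate_phospho_dependence(calls: pd.DataFrame) -> pd.DataFrame:
    """Pair wild-type calls with kinase-dead partners on the same plate."""
    out = calls.copy()
    out["phospho_dependent"] = None
    kd = calls[calls["construct_type"] == "kinase_dead"].set_index("kinase", drop=False)
    for idx, row in out.iterrows():
        if row["construct_type"] != "wt" or row["kinase"] not in kd.index:
            continue
        out.at[idx, "phospho_dependent"] = phospho_dependence(row, kd.loc[row["kinase"]])
    return out
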