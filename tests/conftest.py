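"""Shared fixtures: a hand-built miniature screen dataset and a default
synthetic screen run once per session (it backs several recovery tests)."""

from __future__ import annotations

import pandas as pd
import pytest

from kinarray import condition_qc, screen_model
from kinarray.synthetic_screen import SimConfig, simulate_screen


@pytest.fixture
def tiny_tables():
    """A minimal, fully consistent screen: 2 kinases, 1 control, 1 kinase-dead
    variant, 2 strains, 3 conditions (C3 not evaluated in S2)."""
    scores = pd.DataFrame(
        [
            # KA: two clones; defect in C1/S1, clean elsewhere
            ("KA", "KA_c1", "no_nls", "S1", "C1", 1, 3),
            ("KA", "KA_c2", "nls", "S1", "C1", 1, 1),
            ("KA", "KA_c1", "no_nls", "S1", "C2", 1, 0),
            ("KA", "KA_c1", "no_nls", "S2", "C1", 1, 2),
            ("KA", "KA_c1", "no_nls", "S2", "C2", 1, 0),
            # KB: clean
            ("KB", "KB_c1", "no_nls", "S1", "C1", 1, 0),
            ("KB", "KB_c1", "no_nls", "S1", "C2", 1, 0),
            ("KB", "KB_c1", "no_nls", "S2", "C1", 1, 0),
            ("KB", "KB_c1", "no_nls", "S2", "C2", 1, 0),
            # control and kinase-dead
            ("CT", "CT_c1", "no_nls", "S1", "C1", 1, 0),
            ("KA-KD", "KAKD_c1", "no_nls", "S1", "C1", 1, 0),
            # C3 evaluated in S1 only
            ("KA", "KA_c1", "no_nls", "S1", "C3", 1, 1),
        ],
        columns=screen_model.SCORE_COLUMNS,
    )
    constructs = pd.DataFrame(
        [
            ("KA_c1", "KA", "orf1", "no_nls", False, False),
            ("KA_c2", "KA", "orf2", "nls", False, False),
            ("KB_c1", "KB", "orf3", "no_nls", False, False),
            ("CT_c1", "CT", "orf4", "no_nls", True, False),
            ("KAKD_c1", "KA-KD", "orf5", "no_nls", True, True),
        ],
        columns=screen_model.CONSTRUCT_COLUMNS,
    )
    conditions = pd.DataFrame(
        {
            "condition_id": ["C1", "C2", "C3"],
            "treatment": ["t1", "t2", "t3"],
            "additive": ["", "", ""],
            "concentration": [1.0, 2.0, 3.0],
            "unit": ["mM", "mM", "mM"],
            "temperature": [30.0, 30.0, 37.0],
            "evaluated_S1": [1, 1, 1],
            "evaluated_S2": [1, 1, 0],
        }
    )
    annotations = pd.DataFrame(
        [
            ("KA", "TK", "tyrosine", False, False, False, False, True),
            ("KB", "CMGC", "serine_threonine", True, False, False, True, False),
            ("CT", "control", "", False, True, False, False, False),
            ("KA-KD", "TK", "tyrosine", False, True, True, False, False),
        ],
        columns=screen_model.ANNOTATION_COLUMNS,
    )
    return scores, constructs, conditions, annotations


@pytest.fixture(scope="session")
def default_screen():
    """The reference-scale synthetic screen (fixed seed), simulated once."""
    dataset, truth = simulate_screen(SimConfig(seed=20260921))
    return dataset, truth


@pytest.fixture(scope="session")
def default_screen_qc(default_screen):
    """Aggregated matrix, defect counts, and QC split of the default screen."""
    dataset, truth = default_screen
    matrix = screen_model.aggregate_to_kinase(dataset.scores, dataset.constructs, rule="max")
    counts = condition_qc.defect_counts(
        matrix, defect_min_score=1, restrict_to="kinases_only", annotations=dataset.annotations
    )
    retained, excluded = condition_qc.filter_conditions(counts)
    return dataset, truth, matrix, retained, excluded
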