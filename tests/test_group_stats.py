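"""Group fractions and the self-contained Mann-Whitney rank-sum test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from kinarray import group_stats as gs


def _matrix(rows):
    return pd.DataFrame(rows, columns=["protein_id", "strain", "condition_id", "score"])


def _annotations(proteins):
    """proteins: list of (protein_id, is_control, residue_class, ortholog)."""
    return pd.DataFrame(
        {
            "protein_id": [p[0] for p in proteins],
            "family_group": "g",
            "residue_class": [p[2] for p in proteins],
            "yeast_ortholog": [p[3] for p in proteins],
            "is_control": [p[1] for p in proteins],
            "is_kinase_dead": False,
            "is_dark": False,
            "is_cancer": False,
        }
    )


class TestGroupFractions:
    def test_quarter_fraction(self):
        matrix = _matrix(
            [(f"K{i}", "S1", "C1", s) for i, s in enumerate([3, 0, 0, 0])]
            + [("CT", "S1", "C1", 0)]
        )
        ann = _annotations(
            [(f"K{i}", False, "serine_threonine", False) for i in range(4)]
            + [("CT", True, "", False)]
        )
        fractions = gs.group_fractions(matrix, ann, "kinase_vs_control", severity=1)
        kin = fractions[fractions["group"] == "kinase"]
        assert kin["fraction"].item() == pytest.approx(0.25)
        assert kin["n_members"].item() == 4

    def test_severity_above_all_scores_gives_zero(self):
        matrix = _matrix([("K1", "S1", "C1", 2), ("CT", "S1", "C1", 1)])
        ann = _annotations([("K1", False, "serine_threonine", False), ("CT", True, "", False)])
        fractions = gs.group_fractions(matrix, ann, "kinase_vs_control", severity=3)
        assert (fractions["fraction"] == 0).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        proteins = [(f"K{i}", False, "serine_threonine", bool(i % 2)) for i in range(12)]
        proteins += [(f"C{i}", True, "", False) for i in range(4)]
        ann = _annotations(proteins)
        rows = [
            (p[0], s, f"C{c}", int(rng.integers(0, 4)))
            for p in proteins
            for s in ("S1", "S2")
            for c in range(3)
        ]
        matrix = _matrix(rows)
        fractions = gs.group_fractions(matrix, ann, "kinase_vs_control", severity=2)
        for _, row in fractions.iterrows():
            members = [
                p[0] for p in proteins if (p[1] is (row["group"] == "control"))
            ]
            sub = matrix[
                (matrix["strain"] == row["strain"])
                & (matrix["condition_id"] == row["condition_id"])
                & matrix["protein_id"].isin(members)
            ]
            assert row["fraction"] == pytest.approx((sub["score"] >= 2).mean())

    def test_ortholog_classes_partition_kinases(self):
        ann = _annotations(
            [
                ("TY", False, "tyrosine", False),
                ("OR", False, "serine_threonine", True),
                ("NO", False, "serine_threonine", False),
                ("CT", True, "", False),
            ]
        )
        matrix = _matrix([(p, "S1", "C1", 1) for p in ("TY", "OR", "NO", "CT")])
        fractions = gs.group_fractions(matrix, ann, "ortholog_classes", severity=1)
        assert set(fractions["group"]) == {"tyrosine", "st_ortholog", "st_non_ortholog"}

    def test_empty_group_rejected(self):
        ann = _annotations([("K1", False, "serine_threonine", False)])
        matrix = _matrix([("K1", "S1", "C1", 1)])
        with pytest.raises(ValueError):
            gs.group_fractions(matrix, ann, "kinase_vs_control")


class TestRankSumTest:
    def test_fully_separated_small_samples_exact(self):
        u, p = gs.rank_sum_test([1, 2, 3], [4, 5, 6], "two_sided", "exact")
        assert u == 0
        assert p == pytest.approx(2 / 20)

    def test_identical_multisets_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = gs.rank_sum_test(x, x, "two_sided", "exact")
        assert u == len(x) ** 2 / 2
        assert p >= 0.99

    def test_two_sided_dominates_favoured_one_sided(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(0.5, 1, 6).tolist()
            y = rng.normal(0, 1, 5).tolist()
            _, p2 = gs.rank_sum_test(x, y, "two_sided", "exact")
            _, pg = gs.rank_sum_test(x, y, "greater", "exact")
            _, pl = gs.rank_sum_test(x, y, "less", "exact")
            assert p2 >= min(pg, pl) - 1e-12
            assert 0 <= p2 <= 1 and 0 <= pg <= 1 and 0 <= pl <= 1

    def test_exact_beyond_bound_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15).tolist()
        y = rng.normal(size=15).tolist()
        with pytest.warns(UserWarning, match="enumeration bound"):
            u, p = gs.rank_sum_test(x, y, method="exact")
        assert 0 <= p <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            gs.rank_sum_test([], [1.0])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(0, 5), min_size=2, max_size=5),
        y=st.lists(st.integers(0, 5), min_size=2, max_size=5),
        alternative=st.sampled_from(["two_sided", "greater", "less"]),
    )
    def test_exact_p_matches_scipy_permutation_null(self, x, y, alternative):
        """Exact p equals independent full-permutation enumeration (scipy),
        including tied data."""
        u, p = gs.rank_sum_test(x, y, alternative, "exact")
        scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
        ref = stats.mannwhitneyu(
            x,
            y,
            alternative=scipy_alt[alternative],
            method=stats.PermutationMethod(n_resamples=10**9),
        )
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approx_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0.3, 1, 25)
            u, p = gs.rank_sum_test(x, y, "two_sided", "normal_approx")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_handles_heavy_ties_like_scipy(self):
        rng = np.random.default_rng(23)
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 3, 35)
        u, p = gs.rank_sum_test(x, y, "greater", "normal_approx")
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_i_error_iid_normal(self):
        """At alpha=0.05 the rejection rate under iid normal nulls is nominal."""
        rng = np.random.default_rng(101)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            _, p = gs.rank_sum_test(x, y, "two_sided", "normal_approx")
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestCompareGroups:
    @staticmethod
    def _fractions(a_vals, b_vals):
        rows = []
        for i, v in enumerate(a_vals):
            rows.append((f"C{i}", "S1", "A", v, 10))
        for i, v in enumerate(b_vals):
            rows.append((f"C{i}", "S1", "B", v, 10))
        return pd.DataFrame(
            rows, columns=["condition_id", "strain", "group", "fraction", "n_members"]
        )

    def test_identical_groups_not_significant(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        report = gs.compare_groups(self._fractions(vals, vals), [("A", "B")])
        assert report["p_value"].item() > 0.9

    def test_single_pair_uses_exact_method(self):
        report = gs.compare_groups(self._fractions([0.4], [0.1]), [("A", "B")])
        assert report["method"].item() == "exact"
        assert report["n_a"].item() == 1

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            gs.compare_groups(self._fractions([0.1], [0.2]), [("A", "Z")])

    def test_planted_class_effect_detected(self, default_screen_qc):
        """With a larger planted tyrosine coefficient, the tyrosine vs
        non-ortholog S/T comparison is significant at alpha = 0.01."""
        from kinarray.condition_qc import retained_pair_set

        dataset, truth, matrix, retained, _ = default_screen_qc
        fractions = gs.group_fractions(
            matrix,
            dataset.annotations,
            "ortholog_classes",
            severity=3,
            retained_pairs=retained_pair_set(retained),
        )
        report = gs.compare_groups(
            fractions, [("tyrosine", "st_non_ortholog")], alternative="greater"
        )
        assert report["p_value"].item() < 0.01


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.uniform(0, 1, 25)
    adjusted = gs.benjamini_hochberg(p)
    _, expected, *_ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(adjusted, expected)
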