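"""Data model: parsing, plate grids, clone aggregation, dataset validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


from kinarray import screen_model as sm


def _write(path, text):
    path.write_text(text)
    return path


class TestReadScreenLong:
    def test_well_formed_table_parses_identity(self, tmp_path, tiny_tables):
        scores, *_ = tiny_tables
        path = tmp_path / "scores.tsv"
        sm.write_screen_long(scores, path)
        back = sm.read_screen_long(path)
        pd.testing.assert_frame_equal(back, scores)

    def test_four_rows_give_four_observations(self, tmp_path):
        path = _write(
            tmp_path / "t.tsv",
            "protein_id\tconstruct_id\tvector\tstrain\tcondition_id\treplicate\tscore\n"
            + "".join(f"P\tP_c1\tnls\tS1\tC{i}\t1\t{i % 4}\n" for i in range(4)),
        )
        assert len(sm.read_screen_long(path)) == 4

    def test_out_of_range_score_names_row(self, tmp_path):
        path = _write(
            tmp_path / "bad.tsv",
            "construct_id\tstrain\tcondition_id\treplicate\tscore\n"
            "a\tS1\tC1\t1\t2\n"
            "b\tS1\tC1\t1\t5\n",
        )
        with pytest.raises(sm.ValidationError, match=r"\[1\]"):
            sm.read_screen_long(path)

    def test_empty_file_returns_empty_collection(self, tmp_path, caplog):
        path = _write(tmp_path / "empty.tsv", "")
        with caplog.at_level("WARNING"):
            obs = sm.read_screen_long(path)
        assert obs.empty and list(obs.columns) == sm.SCORE_COLUMNS
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = _write(tmp_path / "bad.tsv", "construct_id\tstrain\n" "a\tS1\n")
        with pytest.raises(sm.SchemaError, match="score"):
            sm.read_screen_long(path)

    def test_schema_mapping_renames_columns(self, tmp_path):
        path = _write(
            tmp_path / "alt.tsv",
            "clone\tbackground\tcond\trep\tvalue\n" "a\tS1\tC1\t1\t2\n",
        )
        obs = sm.read_screen_long(
            path,
            schema={
                "construct_id": "clone",
                "strain": "background",
                "condition_id": "cond",
                "replicate": "rep",
                "score": "value",
            },
        )
        assert obs.loc[0, "score"] == 2 and obs.loc[0, "strain"] == "S1"


class TestPlateGrid:
    @staticmethod
    def _grid_text(n_rows, n_cols, value="0", blank_at=None):
        header = "\t" + "\t".join(str(c) for c in range(1, n_cols + 1))
        lines = [header]
        for i in range(n_rows):
            row = sm.PLATE_384_ROWS[i]
            cells = [value] * n_cols
            if blank_at and blank_at[0] == row:
                cells[blank_at[1] - 1] = ""
            lines.append(row + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"

    @staticmethod
    def _full_layout(n_rows, n_cols):
        return {
            (sm.PLATE_384_ROWS[i], j + 1): f"c{i}_{j}"
            for i in range(n_rows)
            for j in range(n_cols)
        }

    def test_full_384_grid(self, tmp_path):
        path = _write(tmp_path / "g.tsv", self._grid_text(16, 24))
        obs = sm.read_plate_grid(path, self._full_layout(16, 24), "S1", "C1")
        assert len(obs) == 384 and (obs["score"] == 0).all()

    def test_blank_cell_is_missing_not_zero(self, tmp_path):
        path = _write(tmp_path / "g.tsv", self._grid_text(16, 24, blank_at=("B", 3)))
        obs = sm.read_plate_grid(path, self._full_layout(16, 24), "S1", "C1")
        assert len(obs) == 383

    def test_96_format_with_declared_dimensions(self, tmp_path):
        path = _write(tmp_path / "g.tsv", self._grid_text(8, 12, value="1"))
        obs = sm.read_plate_grid(
            path, self._full_layout(8, 12), "S1", "C1", n_rows=8, n_cols=12
        )
        assert len(obs) == 96 and (obs["score"] == 1).all()

    def test_wrong_dimensions_raise(self, tmp_path):
        path = _write(tmp_path / "g.tsv", self._grid_text(8, 12))
        with pytest.raises(sm.SchemaError):
            sm.read_plate_grid(path, self._full_layout(8, 12), "S1", "C1")


class TestAggregateToKinase:
    def test_max_takes_any_active_clone(self, tiny_tables):
        scores, constructs, *_ = tiny_tables
        matrix = sm.aggregate_to_kinase(scores, constructs, rule="max")
        val = matrix.query("protein_id == 'KA' and strain == 'S1' and condition_id == 'C1'")
        assert val["score"].item() == 3

    @pytest.mark.parametrize("rule,expected", [("median", 1), ("max", 3)])
    def test_six_scores_aggregate(self, rule, expected):
        # 3 clones x 2 replicates with scores {0,1,1,2,0,3}
        obs = pd.DataFrame(
            {
                "construct_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
                "strain": "S1",
                "condition_id": "C1",
                "replicate": [1, 2, 1, 2, 1, 2],
                "score": [0, 1, 1, 2, 0, 3],
            }
        )
        constructs = pd.DataFrame(
            {
                "construct_id": ["c1", "c2", "c3"],
                "protein_id": "P",
                "orf_clone": ["o1", "o2", "o3"],
                "vector": "nls",
                "is_control": False,
                "is_kinase_dead": False,
            }
        )
        matrix = sm.aggregate_to_kinase(obs, constructs, rule=rule)
        assert matrix["score"].item() == expected

    def test_kinase_dead_never_pools_with_wild_type(self, tiny_tables):
        scores, constructs, *_ = tiny_tables
        matrix = sm.aggregate_to_kinase(scores, constructs)
        assert "KA-KD" in set(matrix["protein_id"])
        kd = matrix.query("protein_id == 'KA-KD'")["score"]
        assert (kd == 0).all()

    def test_undeclared_construct_raises(self, tiny_tables):
        scores, constructs, *_ = tiny_tables
        with pytest.raises(sm.IntegrityError):
            sm.aggregate_to_kinase(scores, constructs.iloc[1:], rule="max")

    def test_max_rule_invariant_to_row_order_and_dominates_spots(self, tiny_tables):
        scores, constructs, *_ = tiny_tables
        base = sm.aggregate_to_kinase(scores, constructs, rule="max")
        rng = np.random.default_rng(42)
        for _ in range(20):
            shuffled = scores.iloc[rng.permutation(len(scores))].reset_index(drop=True)
            perm = sm.aggregate_to_kinase(shuffled, constructs, rule="max")
            pd.testing.assert_frame_equal(base, perm)
        # idempotence: aggregating the aggregate is the identity
        as_obs = base.assign(construct_id=base["protein_id"] + "_c1", replicate=1)
        as_obs = as_obs[["construct_id", "strain", "condition_id", "replicate", "score"]]
        identity_constructs = constructs.assign(
            construct_id=constructs["protein_id"] + "_c1"
        ).drop_duplicates("construct_id")
        again = sm.aggregate_to_kinase(as_obs, identity_constructs, rule="max")
        pd.testing.assert_frame_equal(again, base)
        # aggregated value dominates every contributing spot
        lookup = base.set_index(["protein_id", "strain", "condition_id"])["score"]
        for _, row in scores.iterrows():
            protein = constructs.set_index("construct_id")["protein_id"][row["construct_id"]]
            assert lookup[(protein, row["strain"], row["condition_id"])] >= row["score"]


class TestValidateDataset:
    def test_consistent_fixture_is_clean(self, tiny_tables):
        report = sm.validate_dataset(*tiny_tables)
        assert report.ok
        assert report.per_strain_counts == {"S1": 8, "S2": 4}

    def test_not_evaluated_strain_flagged(self, tiny_tables):
        scores, constructs, conditions, annotations = tiny_tables
        extra = scores.iloc[[0]].assign(strain="S2", condition_id="C3")
        report = sm.validate_dataset(
            pd.concat([scores, extra], ignore_index=True), constructs, conditions, annotations
        )
        assert len(report.issues) == 1 and "not flagged as evaluated" in report.issues[0]

    def test_planted_duplicates_each_reported(self, tiny_tables):
        scores, constructs, conditions, annotations = tiny_tables
        dup = pd.concat([scores, scores.iloc[[0, 5]]], ignore_index=True)
        report = sm.validate_dataset(dup, constructs, conditions, annotations)
        dup_issues = [i for i in report.issues if i.startswith("duplicate observation")]
        assert len(dup_issues) == 2

    def test_orphan_references_reported(self, tiny_tables):
        scores, constructs, conditions, annotations = tiny_tables
        report = sm.validate_dataset(
            scores, constructs.iloc[1:], conditions, annotations
        )
        assert any("orphan construct" in i for i in report.issues)


def test_condition_round_trip_and_evaluated_in(tmp_path, tiny_tables):
    _, _, conditions, _ = tiny_tables
    path = tmp_path / "cond.tsv"
    sm.write_conditions(conditions, path)
    back = sm.read_conditions(path)
    assert sm.condition_strains(back) == ["S1", "S2"]
    ev = sm.evaluated_in(back)
    assert ev["C3"] == {"S1"} and ev["C1"] == {"S1", "S2"}
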