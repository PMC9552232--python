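"""Filtering rules, log2/imputation arithmetic, QC and overlap sets."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepmatrix import design_io, preprocess

from conftest import make_pg_table


@pytest.fixture()
def clean_table(tiny_design):
    rng = np.random.default_rng(0)
    return make_pg_table(tiny_design, lfq=rng.uniform(1e6, 1e8, size=(8, 6)))


class TestFilterProteinGroups:
    def test_one_row_per_rule(self, tiny_design):
        lfq = np.full((6, 6), 1e6)
        table = make_pg_table(
            tiny_design, lfq,
            meta={
                "protein_ids": ["REV_P1", "CON_P2", "P3", "P4", "iRT_pep", "P6"],
                "reverse": [True, False, False, False, False, False],
                "contaminant": [False, True, False, False, False, False],
                "only_by_site": [False, False, True, False, False, False],
                "razor_unique_peptides": [5, 5, 5, 1, 5, 5],
            },
        )
        out = preprocess.filter_protein_groups(table, tiny_design)
        assert list(out.meta["protein_ids"]) == ["P6"]
        removed = out.provenance[-1]["removed"]
        assert removed == {
            "reverse": 1, "contaminant": 1, "only_by_site": 1,
            "min_razor_unique": 1, "irt": 1,
        }

    def test_all_clean_is_identity(self, clean_table):
        out = preprocess.filter_protein_groups(clean_table)
        assert out.equals(clean_table)

    def test_survivors_match_independent_rescan(self, small_tables):
        table, design, _ = small_tables
        out = preprocess.filter_protein_groups(table, design)
        expected = 0
        for gid in table.group_ids:
            row = table.meta.loc[gid]
            bad = (
                row["reverse"] or row["contaminant"] or row["only_by_site"]
                or row["razor_unique_peptides"] < 2
                or "iRT" in row["protein_ids"] or "Biognosys" in row["protein_ids"]
            )
            expected += not bad
        assert len(out.meta) == expected

    def test_empty_result_is_hard_error(self, tiny_design):
        table = make_pg_table(
            tiny_design, np.full((2, 6), 1e6), meta={"reverse": [True, True]}
        )
        with pytest.raises(preprocess.PreprocessError, match="all rows filtered"):
            preprocess.filter_protein_groups(table)

    def test_rule_order_invariance(self, small_tables):
        """Survivor sets agree when rules are applied one at a time, any order."""
        table, design, _ = small_tables
        joint = preprocess.filter_protein_groups(table, design)
        meta = table.meta
        rules = {
            "reverse": meta["reverse"],
            "contaminant": meta["contaminant"],
            "only_by_site": meta["only_by_site"],
            "razor": meta["razor_unique_peptides"] < 2,
            "irt": meta["protein_ids"].str.contains("iRT|Biognosys"),
        }
        for order in itertools.islice(itertools.permutations(rules), 5):
            keep = pd.Series(True, index=meta.index)
            for rule in order:
                keep &= ~rules[rule]
            assert set(meta.index[keep]) == set(joint.group_ids)


class TestMaskAndTransform:
    def test_masking_rules(self, tiny_design):
        id_type = [[design_io.ID_BY_MSMS, design_io.ID_BY_MATCHING,
                    design_io.ID_BY_MSMS] * 2]
        msms = [[1, 0, 1] * 2]
        table = make_pg_table(tiny_design, [[2.0**21] * 6], id_type, msms)
        masked = preprocess.mask_non_msms(table)
        assert not masked.masked.iloc[0, 0]
        assert masked.masked.iloc[0, 1]
        # intensities preserved for audit
        assert masked.lfq.iloc[0, 1] == 2.0**21

    def test_masked_fraction_equals_cell_count(self, small_tables):
        table, _, _ = small_tables
        masked = preprocess.mask_non_msms(table)
        frac = (table.id_type != design_io.ID_BY_MSMS).to_numpy().mean()
        assert masked.provenance[-1]["masked_fraction"] == pytest.approx(frac)

    def test_log2_values(self, tiny_design):
        table = make_pg_table(tiny_design, [[2.0**21, 0.0] + [2.0**20] * 4])
        mat = preprocess.log2_transform(table)
        assert mat.values.iloc[0, 0] == pytest.approx(21.0)
        assert np.isnan(mat.values.iloc[0, 1])
        assert not mat.valid.iloc[0, 1]

    def test_log2_inverse(self, clean_table):
        mat = preprocess.log2_transform(clean_table)
        np.testing.assert_allclose(
            np.exp2(mat.values.to_numpy()), clean_table.lfq.to_numpy(), rtol=1e-9
        )

    def test_masked_cell_missing_after_transform(self, tiny_design):
        id_type = [[design_io.ID_BY_MATCHING] + [design_io.ID_BY_MSMS] * 5]
        table = make_pg_table(tiny_design, [[1e6] * 6], id_type, [[0, 1, 1, 1, 1, 1]])
        mat = preprocess.log2_transform(preprocess.mask_non_msms(table))
        assert np.isnan(mat.values.iloc[0, 0])


class TestValidValueFilter:
    def _matrix(self, tiny_design, valid_pattern):
        vals = np.where(valid_pattern, 25.0, np.nan)
        idx = pd.Index([f"P{i}" for i in range(len(vals))], name="group_id")
        return preprocess.LogIntensityMatrix(
            values=pd.DataFrame(vals, index=idx, columns=tiny_design.samples),
            valid=pd.DataFrame(np.asarray(valid_pattern, bool), index=idx,
                               columns=tiny_design.samples),
        )

    def test_boundary_kept_and_dropped(self, tiny_design):
        pattern = [
            [1, 1, 1, 0, 0, 0],  # 3 valid in method A -> kept
            [1, 1, 0, 1, 1, 0],  # 2 valid in each -> dropped
        ]
        out = preprocess.valid_value_filter(self._matrix(tiny_design, pattern),
                                            tiny_design)
        assert list(out.values.index) == ["P0"]

    def test_matches_brute_force(self, tiny_design):
        rng = np.random.default_rng(3)
        pattern = rng.random((200, 6)) < 0.5
        out = preprocess.valid_value_filter(self._matrix(tiny_design, pattern),
                                            tiny_design)
        expected = [
            i for i in range(200)
            if pattern[i, :3].sum() >= 3 or pattern[i, 3:].sum() >= 3
        ]
        assert list(out.values.index) == [f"P{i}" for i in expected]

    def test_monotone_in_min_valid(self, tiny_design):
        rng = np.random.default_rng(4)
        pattern = rng.random((100, 6)) < 0.6
        mat = self._matrix(tiny_design, pattern)
        survivors3 = set(preprocess.valid_value_filter(mat, tiny_design, 3).values.index)
        survivors2 = set(preprocess.valid_value_filter(mat, tiny_design, 2).values.index)
        assert survivors3 <= survivors2


class TestImputation:
    def _matrix(self, tiny_design, vals):
        vals = np.asarray(vals, float)
        idx = pd.Index([f"P{i}" for i in range(len(vals))], name="group_id")
        return preprocess.LogIntensityMatrix(
            values=pd.DataFrame(vals, index=idx, columns=tiny_design.samples),
            valid=pd.DataFrame(~np.isnan(vals), index=idx,
                               columns=tiny_design.samples),
        )

    def test_floor_of_global_minimum(self, tiny_design):
        mat = self._matrix(tiny_design, [[21.0, np.nan, 25.0, 30.0, 24.0, np.nan]])
        out = preprocess.impute_constant(mat)
        assert out.imputation_constant == 21
        assert out.values.iloc[0, 1] == 21.0

    def test_fractional_minimum_floored(self, tiny_design):
        mat = self._matrix(tiny_design, [[21.7, np.nan] + [30.0] * 4])
        out = preprocess.impute_constant(mat)
        assert out.imputation_constant == 21

    def test_complete_matrix_unchanged_constant_recorded(self, tiny_design):
        mat = self._matrix(tiny_design, [[22.5, 23.0, 24.0, 25.0, 26.0, 27.0]])
        out = preprocess.impute_constant(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)
        assert out.imputation_constant == 22

    def test_valid_cells_never_altered(self, tiny_design):
        rng = np.random.default_rng(5)
        vals = rng.uniform(20, 35, size=(50, 6))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        mat = self._matrix(tiny_design, vals)
        out = preprocess.impute_constant(mat)
        mask = mat.valid.to_numpy()
        np.testing.assert_array_equal(
            out.values.to_numpy()[mask], mat.values.to_numpy()[mask]
        )
        imputed = out.values.to_numpy()[~mask]
        assert (imputed == out.imputation_constant).all()

    def test_no_valid_cells_is_error(self, tiny_design):
        mat = self._matrix(tiny_design, [[np.nan] * 6])
        with pytest.raises(preprocess.PreprocessError, match="no valid cells"):
            preprocess.impute_constant(mat)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.one_of(st.just(float("nan")), st.floats(10.0, 40.0)),
                min_size=6, max_size=6,
            ),
            min_size=1, max_size=8,
        )
    )
    def test_constant_is_floor_of_minimum_for_any_matrix(self, rows):
        rows = np.asarray(rows, float)
        if not np.isfinite(rows).any():
            return
        idx = pd.Index([f"P{i}" for i in range(len(rows))], name="group_id")
        cols = [f"{m}{r}" for m in "AB" for r in (1, 2, 3)]
        mat = preprocess.LogIntensityMatrix(
            values=pd.DataFrame(rows, index=idx, columns=cols),
            valid=pd.DataFrame(~np.isnan(rows), index=idx, columns=cols),
        )
        out = preprocess.impute_constant(mat)
        assert out.imputation_constant == math.floor(np.nanmin(rows))
        assert not out.values.isna().any().any()


class TestSummedIntensityQc:
    def test_identical_columns_unflagged(self, tiny_design):
        table = make_pg_table(tiny_design, np.full((10, 6), 1e6))
        qc = preprocess.summed_intensity_qc(table, tiny_design)
        assert not qc["flagged"].any()

    def test_scaled_column_flagged(self, tiny_design):
        lfq = np.full((10, 6), 1e6)
        lfq[:, 2] *= 4
        table = make_pg_table(tiny_design, lfq)
        qc = preprocess.summed_intensity_qc(table, tiny_design)
        assert qc["flagged"].tolist() == [False, False, True, False, False, False]

    def test_sums_match_column_totals(self, small_tables):
        table, design, _ = small_tables
        qc = preprocess.summed_intensity_qc(table, design)
        for s in design.samples:
            assert qc.loc[s, "summed_intensity"] == pytest.approx(
                float(table.lfq[s].sum())
            )


class TestOverlapSets:
    def _table(self, tiny_design, membership):
        """membership: proteins x methods bool; replicates copy the method."""
        membership = np.asarray(membership, bool)
        id_type = np.repeat(
            np.where(membership, design_io.ID_BY_MSMS, design_io.ID_ABSENT), 3, axis=1
        )
        lfq = np.where(id_type == design_io.ID_BY_MSMS, 1e6, 0.0)
        msms = np.where(id_type == design_io.ID_BY_MSMS, 2, 0)
        return make_pg_table(tiny_design, lfq, id_type, msms)

    def test_identical_sets_full_overlap(self, tiny_design):
        table = self._table(tiny_design, [[1, 1]] * 5)
        report = preprocess.overlap_sets(table, tiny_design)
        row = report.collections.iloc[0]
        assert row["percent_overlap"] == 100.0

    def test_disjoint_sets_zero_overlap(self, tiny_design):
        table = self._table(tiny_design, [[1, 0], [0, 1]])
        report = preprocess.overlap_sets(table, tiny_design)
        assert report.collections.iloc[0]["percent_overlap"] == 0.0

    def test_min_reps_threshold(self, tiny_design):
        # protein seen by MS/MS in only 1 of 3 replicates of A
        id_type = [[design_io.ID_BY_MSMS, design_io.ID_ABSENT, design_io.ID_ABSENT,
                    design_io.ID_ABSENT, design_io.ID_ABSENT, design_io.ID_ABSENT]]
        lfq = [[1e6, 0, 0, 0, 0, 0]]
        table = make_pg_table(tiny_design, lfq, id_type, [[2, 0, 0, 0, 0, 0]])
        report = preprocess.overlap_sets(table, tiny_design, min_reps=2)
        assert report.sets["A"] == frozenset()
        report1 = preprocess.overlap_sets(table, tiny_design, min_reps=1)
        assert report1.sets["A"] == frozenset({"P0"})

    def test_counts_match_exhaustive_enumeration(self, design):
        rng = np.random.default_rng(6)
        methods = design.methods[:6]
        sub = design_io.SampleDesign(
            design.table[design.table["method"].isin(methods)].reset_index(drop=True)
        )
        membership = rng.random((120, 6)) < 0.5
        id_type = np.repeat(
            np.where(membership, design_io.ID_BY_MSMS, design_io.ID_ABSENT), 3, axis=1
        )
        lfq = np.where(id_type == design_io.ID_BY_MSMS, 1e6, 0.0)
        msms = np.where(id_type == design_io.ID_BY_MSMS, 2, 0)
        table = make_pg_table(sub, lfq, id_type, msms)
        collections = {
            "pair": methods[:2], "triple": methods[:3], "all": methods,
        }
        report = preprocess.overlap_sets(table, sub, method_collections=collections)
        # brute force over every protein for each collection
        for _, row in report.collections.iterrows():
            cols = [methods.index(m) for m in collections[row["collection"]]]
            inter = sum(membership[:, cols].all(axis=1))
            union = sum(membership[:, cols].any(axis=1))
            assert row["n_intersection"] == inter
            assert row["n_union"] == union
        # UpSet pattern counts partition the union of all sets
        assert report.upset["count"].sum() == membership.any(axis=1).sum()

    def test_percentage_permutation_invariant(self, tiny_design):
        table = self._table(tiny_design, [[1, 1], [1, 0], [0, 1]])
        a = preprocess.overlap_sets(
            table, tiny_design, method_collections={"c": ["A", "B"]}
        )
        b = preprocess.overlap_sets(
            table, tiny_design, method_collections={"c": ["B", "A"]}
        )
        assert (
            a.collections.iloc[0]["percent_overlap"]
            == b.collections.iloc[0]["percent_overlap"]
        )

    def test_unknown_method_in_collection(self, tiny_design):
        table = self._table(tiny_design, [[1, 1]])
        with pytest.raises(preprocess.PreprocessError, match="unknown methods"):
            preprocess.overlap_sets(
                table, tiny_design, method_collections={"bad": ["A", "Z"]}
            )
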