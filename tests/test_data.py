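import numpy as np
import pandas as pd
import pytest

from longsamgsr.data import (DataValidationError, DesignTable,
                             LongitudinalExpressionSet, assemble_dataset,
                             disassemble, read_design_table,
                             read_expression_table)

from conftest import make_dataset


class TestReadExpressionTable:
    def test_round_trip_small_tsv(self, expr_tsv):
        expr_path, _ = expr_tsv
        raw = read_expression_table(expr_path)
        assert raw.shape == (3, 4)
        assert list(raw.index) == ["g1", "g2", "g3"]
        assert list(raw.columns) == ["sA_t1", "sA_t2", "sB_t1", "sB_t2"]
        assert raw.loc["g3", "sA_t1"] == -1.5

    def test_header_only_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_id\ts1\ts2\n")
        with pytest.raises(DataValidationError, match="no genes"):
            read_expression_table(p)

    def test_na_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "na.tsv"
        p.write_text("gene_id\ts1\ts2\ng1\t1.0\tNA\ng2\t2.0\t3.0\n")
        raw = read_expression_table(p)
        expected_missing = np.array([[False, True], [False, False]])
        assert np.array_equal(raw.isna().to_numpy(), expected_missing)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\ts1\ts2\ng1\t1.0\toops\n")
        with pytest.raises(DataValidationError, match="g1.*s2"):
            read_expression_table(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene_id\ts1\ng1\t1.0\ng1\t2.0\n")
        with pytest.raises(DataValidationError, match="duplicate gene"):
            read_expression_table(p)

    def test_csv_dialect(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("gene_id,s1,s2\ng1,1.0,2.0\n")
        raw = read_expression_table(p, dialect="csv")
        assert raw.loc["g1", "s2"] == 2.0


class TestAssemble:
    def test_full_design_all_present(self, expr_tsv):
        expr_path, design_path = expr_tsv
        ds = assemble_dataset(read_expression_table(expr_path),
                              read_design_table(design_path))
        assert ds.expr.shape == (3, 2, 2)
        assert ds.mask.all()
        assert list(ds.labels) == [1, 0]
        # sample sA_t2 (subject A=0, time 2) carries the 2nd column
        assert ds.expr[0, 0, 1] == 2.0

    def test_missing_timepoint_masked(self, expr_tsv, tmp_path):
        expr_path, _ = expr_tsv
        design = tmp_path / "d.tsv"
        design.write_text(
            "sample_id\tsubject_id\ttime_index\tphenotype\n"
            "sA_t1\tA\t1\t1\nsA_t2\tA\t2\t1\nsB_t1\tB\t1\t0\n")
        ds = assemble_dataset(read_expression_table(expr_path),
                              read_design_table(design))
        assert not ds.mask[:, 1, 1].any()   # B lacks time 2
        assert ds.mask[:, 1, 0].all()
        assert ds.expr[1, 1, 0] == 7.0

    def test_inconsistent_phenotype_rejected(self):
        frame = pd.DataFrame({
            "sample_id": ["s1", "s2"], "subject_id": ["A", "A"],
            "time_index": [1, 2], "phenotype": [0, 1]})
        with pytest.raises(DataValidationError, match="inconsistent phenotype"):
            DesignTable(frame)

    def test_duplicate_subject_time_rejected(self):
        frame = pd.DataFrame({
            "sample_id": ["s1", "s2"], "subject_id": ["A", "A"],
            "time_index": [1, 1], "phenotype": [0, 0]})
        with pytest.raises(DataValidationError, match="duplicate"):
            DesignTable(frame)

    def test_zero_time_index_rejected(self):
        frame = pd.DataFrame({
            "sample_id": ["s1"], "subject_id": ["A"],
            "time_index": [0], "phenotype": [0]})
        with pytest.raises(DataValidationError, match="1-based"):
            DesignTable(frame)

    def test_time_order_is_numeric_not_lexical(self, tmp_path):
        # time 10 must land after time 2 even though "10" < "2" lexically
        expr = tmp_path / "e.tsv"
        expr.write_text("gene_id\ta1\ta2\ta10\tb1\tb2\tb10\n"
                        "g1\t1\t2\t3\t4\t5\t6\n")
        design = tmp_path / "d.tsv"
        design.write_text(
            "sample_id\tsubject_id\ttime_index\tphenotype\n"
            "a1\tA\t1\t1\na2\tA\t2\t1\na10\tA\t10\t1\n"
            "b1\tB\t1\t0\nb2\tB\t2\t0\nb10\tB\t10\t0\n")
        ds = assemble_dataset(read_expression_table(expr),
                              read_design_table(design))
        assert ds.n_times == 10
        assert ds.expr[0, 0, 9] == 3.0
        assert not ds.mask[0, 0, 3:9].any()


class TestRoundTripAndInvariants:
    def test_disassemble_assemble_round_trip(self):
        ds = make_dataset(G=4, n1=3, n0=3, T=3, seed=7)
        ds.mask[:, 1, 2] = False   # subject 1 misses time 3 entirely
        raw, design = disassemble(ds)
        back = assemble_dataset(raw, design)
        assert np.array_equal(back.mask, ds.mask)
        assert np.array_equal(back.labels, ds.labels)
        assert np.allclose(back.expr[back.mask], ds.expr[ds.mask])

    def test_mask_counts_match_design(self):
        ds = make_dataset(G=3, n1=3, n0=4, T=2, seed=3)
        ds.mask[:, 5, 0] = False
        raw, design = disassemble(ds)
        back = assemble_dataset(raw, design)
        for t in range(2):
            for cls in (0, 1):
                from_mask = (back.mask.any(axis=0)[back.labels == cls, t]).sum()
                f = design.frame
                from_design = len(f[(f.time_index == t + 1)
                                    & (f.phenotype == cls)])
                assert from_mask == from_design

    def test_nonfinite_expression_rejected(self):
        expr = np.zeros((1, 4, 1))
        expr[0, 0, 0] = np.inf
        with pytest.raises(DataValidationError, match="finite"):
            LongitudinalExpressionSet(expr, np.ones_like(expr, bool),
                                      np.array([1, 1, 0, 0]))

    def test_class_with_single_measured_subject_unfit_for_analysis(self):
        expr = np.zeros((2, 4, 2))
        mask = np.ones_like(expr, bool)
        mask[:, 0, 1] = False   # only one class-1 subject measured at t2
        ds = LongitudinalExpressionSet(expr, mask, np.array([1, 1, 0, 0]))
        with pytest.raises(DataValidationError, match="fewer than 2"):
            ds.validate_for_analysis()
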