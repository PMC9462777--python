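"""Container, I/O, filtering and normalization behaviour."""
import numpy as np
import pytest

from miprot.quant import (
    PeptideProteinMap,
    QuantTable,
    filter_min_observed,
    filter_shared_peptides,
    load_quant_table,
    quantile_normalize,
    write_quant_table,
)

from conftest import make_table

CONFIG = {"conditions": {"A": ["s1", "s2"], "B": ["s3"]}}


class TestLoading:
    def test_generic_tsv_parses_empty_cell_as_missing(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\ts1\ts2\ts3\np1\t1.5\t\t2.0\np2\t3\t4\t5\np3\t6\t7\t8\n")
        table = load_quant_table(p, CONFIG)
        assert table.mask.sum() == 1
        assert table.mask[0, 1]
        assert table.values[1, 2] == 5.0
        assert table.conditions == ["A", "B"]

    def test_maxquant_zero_intensity_becomes_missing_not_log2_zero(self, tmp_path):
        p = tmp_path / "peptides.txt"
        p.write_text(
            "Sequence\tProteins\tIntensity s1\tIntensity s2\tIntensity s3\n"
            "PEPTIDEA\tP1\t1024\t0\t2048\n"
            "PEPTIDEB\tP1;P2\t512\t512\t512\n"
        )
        table, pep_map = load_quant_table(p, CONFIG, dialect="maxquant_peptides")
        assert np.isnan(table.values[0, 1])
        assert table.values[0, 0] == 10.0  # log2(1024)
        assert pep_map.proteins_of("PEPTIDEB") == frozenset({"P1", "P2"})

    def test_maxquant_contaminants_dropped(self, tmp_path):
        p = tmp_path / "peptides.txt"
        p.write_text(
            "Sequence\tProteins\tReverse\tIntensity s1\tIntensity s2\tIntensity s3\n"
            "AAA\tP1\t\t2\t2\t2\nBBB\tP2\t+\t4\t4\t4\n"
        )
        table, _ = load_quant_table(p, CONFIG, dialect="maxquant_peptides")
        assert table.analyte_ids == ["AAA"]

    def test_unknown_column_in_design_config_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\ts1\ts2\ts3\np1\t1\t2\t3\n")
        bad = {"conditions": {"A": ["s1", "nope"], "B": ["s3"]}}
        with pytest.raises(ValueError, match="unknown columns"):
            load_quant_table(p, bad)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\ts1\ts2\ts3\np1\t1\toops\t3\n")
        with pytest.raises(ValueError, match="s2"):
            load_quant_table(p, CONFIG)

    def test_duplicate_analyte_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            QuantTable(
                np.ones((2, 2)),
                ["p", "p"],
                ["s1", "s2"],
                {"s1": "A", "s2": "B"},
            )

    def test_round_trip_preserves_values_mask_and_ids(self, tmp_path, masked_table):
        p = tmp_path / "t.tsv"
        write_quant_table(masked_table, p)
        cfg = {"conditions": {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}}
        back = load_quant_table(p, cfg)
        assert back.analyte_ids == masked_table.analyte_ids
        assert back.sample_ids == masked_table.sample_ids
        np.testing.assert_array_equal(back.mask, masked_table.mask)
        obs = ~masked_table.mask
        np.testing.assert_allclose(back.values[obs], masked_table.values[obs], rtol=1e-12)


class TestFilterMinObserved:
    def rows_table(self, observed_counts):
        # build 6-sample rows with the requested observed counts per condition
        rows = []
        for n_a, n_b in observed_counts:
            row = [1.0] * n_a + [np.nan] * (3 - n_a) + [2.0] * n_b + [np.nan] * (3 - n_b)
            rows.append(row)
        return make_table(rows, 3, 3)

    def test_row_missing_whole_condition_removed_at_min_one(self):
        table = self.rows_table([(3, 0)])
        assert filter_min_observed(table, 1).n_analytes == 0

    def test_min_zero_is_identity(self):
        table = self.rows_table([(3, 0), (1, 1)])
        out = filter_min_observed(table, 0)
        assert out.analyte_ids == table.analyte_ids

    def test_enumerated_fixture_min_two(self):
        table = self.rows_table([(3, 3), (2, 3), (1, 3), (0, 3), (3, 1)])
        out = filter_min_observed(table, 2)
        assert out.analyte_ids == ["p0", "p1"]

    def test_idempotent_and_order_preserving(self):
        table = self.rows_table([(3, 3), (0, 3), (2, 2), (1, 0), (3, 3)])
        once = filter_min_observed(table, 1)
        twice = filter_min_observed(once, 1)
        assert once.analyte_ids == twice.analyte_ids == ["p0", "p2", "p4"]

    def test_threshold_above_condition_size_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            filter_min_observed(self.rows_table([(3, 3)]), 4)


class TestFilterSharedPeptides:
    MAP = PeptideProteinMap(
        {
            "p0": {"P1"},
            "p1": {"P1", "P2"},
            "p2": {"P3"},
            "p3": {"P1", "P2", "P3"},
        }
    )

    def test_shared_peptides_dropped(self):
        table = make_table(np.ones((4, 4)), 2, 2)
        out = filter_shared_peptides(table, self.MAP)
        assert out.analyte_ids == ["p0", "p2"]

    def test_all_unique_is_identity(self):
        table = make_table(np.ones((2, 4)), 2, 2, ids=["p0", "p2"])
        out = filter_shared_peptides(table, self.MAP)
        assert out.analyte_ids == ["p0", "p2"]

    def test_uncovered_analyte_raises_with_ids(self):
        table = make_table(np.ones((1, 4)), 2, 2, ids=["mystery"])
        with pytest.raises(ValueError, match="mystery"):
            filter_shared_peptides(table, self.MAP)


class TestQuantileNormalize:
    def test_two_columns_average_of_order_statistics(self):
        table = make_table(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]).reshape(3, 2), 1, 1)
        out = quantile_normalize(table)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0])
        table = make_table(np.column_stack([col, col]), 1, 1)
        out = quantile_normalize(table)
        np.testing.assert_allclose(out.values, table.values, atol=1e-12)

    def test_complete_matrix_columns_share_sorted_values(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.normal(size=(40, 6)), 3, 3)
        out = quantile_normalize(table)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-10)

    def test_missing_cells_stay_missing(self, masked_table):
        out = quantile_normalize(masked_table)
        np.testing.assert_array_equal(out.mask, masked_table.mask)

    def test_empty_column_raises(self):
        vals = np.ones((2, 4))
        vals[:, 1] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            quantile_normalize(make_table(vals, 2, 2))
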