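"""Delimited-text round-trips and validation."""

import numpy as np
import pytest

from mrmr_eqtl import (
    EqtlRecord,
    EqtlTable,
    ExpressionMatrix,
    GenotypeMatrix,
    align_samples,
    read_annotation,
    read_eqtl_table,
    read_expression,
    read_genotypes,
    write_eqtl_table,
    write_expression,
    write_genotypes,
)
from mrmr_eqtl.data_io import write_annotation


class TestGenotypeIO:
    def test_round_trip(self, tmp_path, rng):
        g = GenotypeMatrix(
            ["m1", "m2", "m3"],
            ["a", "b", "c", "d"],
            rng.integers(1, 4, size=(3, 4)),
        )
        path = tmp_path / "g.tsv"
        write_genotypes(g, path)
        back = read_genotypes(path)
        assert back.marker_ids == g.marker_ids
        assert back.sample_ids == g.sample_ids
        assert np.array_equal(back.values, g.values)
        assert not back.missing.any()

    def test_missing_token_round_trip(self, tmp_path):
        g = GenotypeMatrix(
            ["m1", "m2"],
            ["a", "b"],
            np.array([[1, 2], [3, 1]]),
            np.array([[False, True], [False, False]]),
        )
        path = tmp_path / "g.tsv"
        write_genotypes(g, path)
        back = read_genotypes(path)
        assert back.missing.tolist() == [[False, True], [False, False]]
        assert back.values[0, 0] == 1

    def test_out_of_range_entry_names_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\ta\tb\nm1\t1\t4\n")
        with pytest.raises(ValueError, match="m1.*b|b.*m1"):
            read_genotypes(path)

    def test_duplicate_marker_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\ta\nm1\t1\nm1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genotypes(path)

    def test_unparseable_cell_becomes_missing(self, tmp_path, caplog):
        path = tmp_path / "odd.tsv"
        path.write_text("id\ta\tb\nm1\t1\t?\n")
        with caplog.at_level("WARNING"):
            g = read_genotypes(path)
        assert g.missing[0, 1]
        assert any("unparseable" in m for m in caplog.messages)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(["m1"], ["a", "b"], np.array([[1, 5]]))
        with pytest.raises(ValueError):
            GenotypeMatrix(["m1", "m1"], ["a"], np.array([[1], [2]]))


class TestExpressionIO:
    def test_round_trip_preserves_12_significant_digits(self, tmp_path, rng):
        e = ExpressionMatrix(
            ["g1", "g2"], ["a", "b", "c"], rng.normal(size=(2, 3)) * 1e3
        )
        path = tmp_path / "e.tsv"
        write_expression(e, path)
        back = read_expression(path)
        assert np.allclose(back.values, e.values, rtol=1e-11)
        assert back.gene_ids == e.gene_ids

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\ta\tb\ng1\t1.5\tpotato\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression(path)

    def test_short_row_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("id\ta\tb\ng1\t1.0\t2.0\ng2\t3.0\n")
        with pytest.raises(ValueError, match="row 2"):
            read_expression(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="no data rows"):
            read_expression(path)


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        ann = {"g1": ("chr1", 100), "g2": ("chr2", 5_000_000)}
        path = tmp_path / "ann.tsv"
        write_annotation(ann, path)
        assert read_annotation(path) == ann

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("id\tchrom\tpos\ng1\tchr1\t10\ng1\tchr2\t20\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(path)

    def test_thousands_separator_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("id\tchrom\tpos\ng1\tchr1\t12,000\n")
        with pytest.raises(ValueError, match="integer"):
            read_annotation(path)


class TestEqtlTableIO:
    def _table(self):
        return EqtlTable(
            [
                EqtlRecord("s2", "g9", 0.8123456789, 0.7, 0.93, "cis", 1500),
                EqtlRecord("s1", "gZ", 0.5, 0.25, 0.91, "trans", None),
                EqtlRecord("s1", "gA", 0.4, 0.10, 0.91, "ambiguous", None),
            ]
        )

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_eqtl_table(EqtlTable([]), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == [
            "snp_id", "gene_id", "relevance_bits", "mrmr_score",
            "loocv_accuracy", "cis_class", "distance_bp",
        ]
        assert len(read_eqtl_table(path)) == 0

    def test_round_trip(self, tmp_path):
        path = tmp_path / "t.tsv"
        table = self._table()
        write_eqtl_table(table, path)
        back = read_eqtl_table(path)
        assert set(back.records) == set(table.records)

    def test_sorted_by_snp_keeping_selection_order(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_eqtl_table(self._table(), path)
        back = read_eqtl_table(path)
        # stable sort oracle: sort by snp only, preserving input order within snp
        expected = sorted(self._table().records, key=lambda r: r.snp_id)
        assert back.records == expected

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            EqtlTable(
                [
                    EqtlRecord("s1", "g1", 0.5, 0.5, 0.9, "cis", 10),
                    EqtlRecord("s1", "g1", 0.6, 0.6, 0.9, "cis", 10),
                ]
            )


class TestAlignSamples:
    def test_sorted_intersection_applied_to_both(self, rng):
        g = GenotypeMatrix(
            ["m1"], ["d", "b", "a", "c"], rng.integers(1, 4, size=(1, 4))
        )
        e = ExpressionMatrix(
            ["g1"], ["c", "e", "a", "b"], rng.normal(size=(1, 4))
        )
        ga, ea = align_samples(g, e)
        assert ga.sample_ids == ea.sample_ids == ["a", "b", "c"]
        for s in ["a", "b", "c"]:
            assert ga.values[0, ga.sample_ids.index(s)] == g.values[0, g.sample_ids.index(s)]
            assert ea.values[0, ea.sample_ids.index(s)] == e.values[0, e.sample_ids.index(s)]

    def test_no_shared_samples_rejected(self, rng):
        g = GenotypeMatrix(["m1"], ["a"], np.array([[1]]))
        e = ExpressionMatrix(["g1"], ["b"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            align_samples(g, e)
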