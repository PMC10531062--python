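"""File-dialect readers/writers: parse contracts and round-trips."""

import numpy as np
import pandas as pd
import pytest

from sexbias import formats
from sexbias.formats import (
    AssociationTable,
    CategorySetCollection,
    ExpressionDataset,
    MiRNAAnnotation,
)


def _write_expr(tmp_path, matrix_lines, meta_lines):
    expr = tmp_path / "expr.tsv"
    meta = tmp_path / "meta.tsv"
    expr.write_text("\n".join(matrix_lines) + "\n")
    meta.write_text("\n".join(meta_lines) + "\n")
    return expr, meta


class TestReadExpression:
    META = [
        "sample_id\tsex\tdisease\tdataset_id",
        "S1\tF\td\tDS1",
        "S2\tF\td\tDS1",
        "S3\tM\td\tDS1",
        "S4\tM\td\tDS1",
    ]

    def test_all_na_row_dropped(self, tmp_path):
        expr, meta = _write_expr(
            tmp_path,
            [
                "mirna\tS1\tS2\tS3\tS4",
                "hsa-mir-1\t1\t2\t3\t4",
                "hsa-mir-2\t\t\t\t",
                "hsa-mir-3\t5\t6\t7\t8",
            ],
            self.META,
        )
        ds = formats.read_expression(expr, meta)
        assert list(ds.matrix.index) == ["hsa-mir-1", "hsa-mir-3"]
        assert ds.dataset_id == "DS1"

    def test_duplicate_probes_mean_merged(self, tmp_path):
        expr, meta = _write_expr(
            tmp_path,
            [
                "mirna\tS1\tS2\tS3\tS4",
                "hsa-miR-9\t1\t1\t1\t1",
                "HSA-MIR-9\t3\t3\t3\t3",
            ],
            self.META,
        )
        ds = formats.read_expression(expr, meta)
        np.testing.assert_allclose(ds.matrix.loc["hsa-mir-9"].to_numpy(), [2, 2, 2, 2])

    def test_sample_missing_from_metadata(self, tmp_path):
        expr, meta = _write_expr(
            tmp_path,
            ["mirna\tS1\tS2\tS9", "hsa-mir-1\t1\t2\t3"],
            self.META,
        )
        with pytest.raises(ValueError, match="S9"):
            formats.read_expression(expr, meta)

    def test_bad_sex_label(self, tmp_path):
        expr, meta = _write_expr(
            tmp_path,
            ["mirna\tS1\tS2", "hsa-mir-1\t1\t2", "hsa-mir-2\t1\t2"],
            ["sample_id\tsex", "S1\tF", "S2\tunknown"],
        )
        with pytest.raises(ValueError, match="sex"):
            formats.read_expression(expr, meta)

    def test_expression_round_trip(self, tmp_path):
        matrix = pd.DataFrame(
            [[1.5, 2.0, 3.0], [0.5, 1.0, 2.5]],
            index=["hsa-mir-1", "hsa-mir-2"],
            columns=["A", "B", "C"],
        )
        ds = ExpressionDataset(
            dataset_id="DS9",
            matrix=matrix,
            sample_sex={"A": "F", "B": "M", "C": "M"},
            disease="x",
        )
        formats.write_expression(ds, tmp_path / "e.tsv", tmp_path / "m.tsv")
        back = formats.read_expression(tmp_path / "e.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.matrix, matrix)
        assert back.sample_sex == ds.sample_sex
        assert back.dataset_id == "DS9"

    def test_minimum_shape_enforced(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionDataset(
                dataset_id="D",
                matrix=pd.DataFrame({"A": [1.0]}, index=["hsa-mir-1"]),
                sample_sex={"A": "F"},
            )


class TestGff3:
    def test_parse_contract(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\t"
            "ID=MI0000001;Name=hsa-mir-test\n"
        )
        ann = formats.read_gff3(path)
        row = ann.table.loc["hsa-mir-test"]
        assert (row["chromosome"], row["start"], row["end"], row["strand"]) == (
            "chr1",
            100,
            180,
            "+",
        )

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(ValueError, match=":2"):
            formats.read_gff3(path)

    def test_round_trip_with_mature_map(self, tmp_path, small_annotation):
        mature_map = {
            name: [f"{name}-5p", f"{name}-3p"]
            for name in list(small_annotation.table.index)[:10]
        }
        path = tmp_path / "rt.gff3"
        formats.write_gff3(small_annotation, path, mature_map)
        back = formats.read_gff3(path)
        pd.testing.assert_frame_equal(back.table, small_annotation.table)
        assert formats.read_mature_map(path) == mature_map

    def test_annotation_invariants(self):
        bad = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [10], "end": [5], "strand": ["+"]},
            index=["hsa-mir-x"],
        )
        with pytest.raises(ValueError, match="start > end"):
            MiRNAAnnotation(table=bad)


class TestMiFam:
    def test_species_set_size(self, tmp_path):
        path = tmp_path / "fam.txt"
        path.write_text(
            "AC   MIPF0000001\n"
            "ID   mir-17\n"
            "MI   MI0000071  hsa-mir-17\n"
            "MI   MI0000687  mmu-mir-17\n"
            "MI   MI0000844  rno-mir-17\n"
            "MI   MI0001165  gga-mir-17\n"
            "//\n"
        )
        families = formats.read_mifam(path)
        members = families["MIPF0000001"]
        assert {m.split("-")[0] for m in members} == {"hsa", "mmu", "rno", "gga"}

    def test_missing_terminator(self, tmp_path):
        path = tmp_path / "fam.txt"
        path.write_text("AC   MIPF0000001\nMI   MI0000071  hsa-mir-17\n")
        with pytest.raises(ValueError, match="terminator"):
            formats.read_mifam(path)

    def test_round_trip(self, tmp_path):
        families = {
            "MIPF0000001": ["hsa-mir-1", "mmu-mir-1", "gga-mir-1"],
            "MIPF0000002": ["hsa-mir-2"],
        }
        path = tmp_path / "fam.txt"
        formats.write_mifam(families, path)
        assert formats.read_mifam(path) == families


class TestSimpleTables:
    def test_associations(self, tmp_path):
        path = tmp_path / "assoc.csv"
        path.write_text("mirna,disease\nhsa-mir-1,flu\nhsa-mir-1,cancer\nhsa-mir-2,flu\n")
        table = formats.read_associations(path)
        assert len(table.pairs) == 3
        assert table.disease_universe == {"flu", "cancer"}

    def test_associations_round_trip(self, tmp_path):
        table = AssociationTable(
            pairs={("hsa-mir-1", "flu"), ("hsa-mir-2", "gout")},
            disease_universe={"flu", "gout"},
        )
        formats.write_associations(table, tmp_path / "a.csv")
        back = formats.read_associations(tmp_path / "a.csv")
        assert back.pairs == table.pairs

    def test_category_sets_round_trip(self, tmp_path):
        colls = {
            "TF": CategorySetCollection(
                class_name="TF",
                sets={"TGFB1": {"hsa-mir-1", "hsa-mir-2"}, "TP53": {"hsa-mir-3"}},
            )
        }
        formats.write_category_sets(colls, tmp_path / "c.tsv")
        back = formats.read_category_sets(tmp_path / "c.tsv")
        assert back["TF"].sets == colls["TF"].sets

    def test_empty_category_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CategorySetCollection(class_name="TF", sets={"X": set()})

    def test_tsi_round_trip_and_domain(self, tmp_path):
        scores = {"hsa-mir-1": 0.3, "hsa-mir-2": 1.0}
        formats.write_tsi(scores, tmp_path / "t.tsv")
        assert formats.read_tsi(tmp_path / "t.tsv") == scores
        (tmp_path / "bad.tsv").write_text("mirna\ttsi\nhsa-mir-1\t1.5\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            formats.read_tsi(tmp_path / "bad.tsv")
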