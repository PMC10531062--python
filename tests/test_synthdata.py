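"""Synthetic-data generator: planted truth, determinism, re-parseability."""

import numpy as np
import pandas as pd
import pytest

from sexbias import formats
from sexbias.synthdata import (
    SynthConfig,
    generate_annotation,
    generate_association_table,
    generate_category_sets,
    generate_expression_dataset,
    generate_family_file,
    generate_tsi_table,
    species_counts_from_conservation,
)


class TestSynthConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mirnas": 0},
            {"n_female": 0},
            {"frac_biased": 1.5},
            {"noise_sd": 0.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestExpression:
    def test_null_configuration(self):
        cfg = SynthConfig(n_mirnas=100, n_female=10, n_male=10, frac_biased=0.0, seed=1)
        _, truth = generate_expression_dataset(cfg)
        assert (truth["planted"] == "unbiased").all()

    def test_planted_counts(self):
        cfg = SynthConfig(
            n_mirnas=100,
            n_female=10,
            n_male=10,
            frac_biased=0.2,
            frac_female_biased_of_biased=0.5,
            seed=1,
        )
        _, truth = generate_expression_dataset(cfg)
        counts = truth["planted"].value_counts()
        assert counts.get("FB", 0) == 10 and counts.get("MB", 0) == 10

    def test_determinism(self):
        cfg = SynthConfig(n_mirnas=80, seed=77)
        ds1, t1 = generate_expression_dataset(cfg)
        ds2, t2 = generate_expression_dataset(cfg)
        pd.testing.assert_frame_equal(ds1.matrix, ds2.matrix)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_truth_consistency(self):
        # a female-shifted miRNA has strictly larger sample mean among
        # female samples at a large planted shift, and symmetrically
        cfg = SynthConfig(n_mirnas=200, n_female=40, n_male=40, effect_size=3.0, seed=5)
        ds, truth = generate_expression_dataset(cfg)
        fcols, mcols = ds.sex_columns("F"), ds.sex_columns("M")
        for _, row in truth[truth["planted"] != "unbiased"].iterrows():
            diff = ds.matrix.loc[row["mirna"], fcols].mean() - ds.matrix.loc[row["mirna"], mcols].mean()
            assert diff > 0 if row["planted"] == "FB" else diff < 0


class TestAnnotation:
    def test_basic_invariants(self):
        ann = generate_annotation(5, n_chromosomes=3, seed=0)
        assert len(ann) == 5
        assert (ann.table["start"] < ann.table["end"]).all()

    def test_zero_sex_share_all_autosomal(self):
        ann = generate_annotation(50, seed=1, sex_chrom_share=0.0)
        assert not ann.table["chromosome"].isin(["chrX", "chrY"]).any()

    def test_cluster_planting(self):
        names = [f"hsa-mir-s{i + 1:04d}" for i in range(40)]
        planted = names[:12]
        span = 10_000
        ann = generate_annotation(
            names, seed=3, sex_chrom_share=0.0, cluster_members=planted, cluster_span_bp=span
        )
        sub = ann.table.loc[planted]
        found = False
        for _, chrom_df in sub.groupby("chromosome"):
            starts = np.sort(chrom_df["start"].to_numpy())
            for i in range(len(starts) - 2):
                if starts[i + 2] - starts[i] <= span:
                    found = True
        assert found, "no chromosome carries >=3 planted miRNAs within the span"

    def test_reparses_through_formats(self, tmp_path, small_annotation):
        formats.write_gff3(small_annotation, tmp_path / "a.gff3")
        back = formats.read_gff3(tmp_path / "a.gff3")
        pd.testing.assert_frame_equal(back.table, small_annotation.table)


class TestFamilies:
    def test_round_trip_property(self, tmp_path, small_annotation):
        counts = species_counts_from_conservation(small_annotation, seed=4)
        families = generate_family_file(small_annotation, counts, seed=4)
        formats.write_mifam(families, tmp_path / "fam.txt")
        assert formats.read_mifam(tmp_path / "fam.txt") == families

    def test_species_counts_honored(self, small_annotation):
        counts = species_counts_from_conservation(small_annotation, seed=4)
        families = generate_family_file(small_annotation, counts, seed=4)
        for accession, members in families.items():
            n_species = len({m.split("-")[0] for m in members})
            # pool depth can cap very large requests; count never exceeds
            # the request and G1 families stay human-only
            assert n_species <= counts[accession] or counts[accession] == 1
            if counts[accession] == 1:
                assert {m.split("-")[0] for m in members} == {"hsa"}

    def test_unknown_family_accession(self, small_annotation):
        with pytest.raises(ValueError, match="unknown family"):
            generate_family_file(small_annotation, {}, seed=0)

    def test_single_member_family_count_one(self, tmp_path):
        formats.write_mifam({"MIPF0000009": ["hsa-mir-9"]}, tmp_path / "f.txt")
        fam = formats.read_mifam(tmp_path / "f.txt")
        assert len({m.split("-")[0] for m in fam["MIPF0000009"]}) == 1


class TestTables:
    def test_density_one_full_table(self):
        table = generate_association_table(["hsa-mir-1", "hsa-mir-2"], n_diseases=4, density=1.0)
        assert len(table.pairs) == 8

    def test_density_zero_empty(self):
        table = generate_association_table(10, n_diseases=5, density=0.0)
        assert not table.pairs and len(table.disease_universe) == 5

    def test_density_out_of_range(self):
        with pytest.raises(ValueError, match="density"):
            generate_association_table(5, density=1.2)

    def test_category_sets_are_subsets(self):
        mirnas = [f"hsa-mir-s{i:04d}" for i in range(1, 51)]
        coll = generate_category_sets(mirnas, n_categories=3, seed=9)
        assert len(coll.sets) == 3
        for members in coll.sets.values():
            assert members <= set(mirnas)

    def test_tsi_in_unit_interval(self):
        scores = generate_tsi_table(100, seed=2, boost={"hsa-mir-s0001": 5.0})
        assert all(0.0 <= v <= 1.0 for v in scores.values())
        assert scores["hsa-mir-s0001"] == 1.0


class TestWorldDeterminism:
    def test_world_files_byte_identical(self, tmp_path):
        from sexbias.pipeline import write_world
        from sexbias.synthdata import generate_world

        cfg = SynthConfig(n_mirnas=60, n_female=8, n_male=8)
        for d in ("w1", "w2"):
            write_world(generate_world(cfg, seed=21), tmp_path / d, seed=21)
        for f1 in sorted((tmp_path / "w1").iterdir()):
            f2 = tmp_path / "w2" / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name
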