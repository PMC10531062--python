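"""Sex-biased calling, conflict-excluding merge, and overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from sexbias.biasid import (
    BiasCatalog,
    SexBiasResult,
    assign_group,
    assign_tissue_class,
    compare_with_baseline,
    identify,
    merge,
    overlap_stats,
)
from sexbias.formats import ExpressionDataset
from sexbias.synthdata import SynthConfig, generate_expression_dataset


def _dataset(values: dict[str, list[float]], n_f: int, n_m: int, ds_id="D1"):
    cols = [f"F{i}" for i in range(n_f)] + [f"M{i}" for i in range(n_m)]
    matrix = pd.DataFrame(values, index=cols).T
    sex = {c: c[0] for c in cols}
    return ExpressionDataset(dataset_id=ds_id, matrix=matrix, sample_sex=sex)


def _result(ds_id, fb=(), mb=()):
    rows = [
        {"mirna": m, "p_two_sided": 0.01, "direction": d, "median_female": 1.0, "median_male": 0.0}
        for d, names in (("FB", fb), ("MB", mb))
        for m in names
    ]
    return SexBiasResult(dataset_id=ds_id, table=pd.DataFrame(rows))


class TestIdentify:
    def test_constant_rows_never_flagged(self):
        ds = _dataset({"hsa-mir-1": [3.0] * 12, "hsa-mir-2": [1.0] * 12}, 6, 6)
        assert identify(ds).table.empty

    def test_direction_follows_medians(self):
        ds = _dataset(
            {"hsa-mir-f": [9, 9, 9, 9, 9, 9, 1, 1, 1, 1, 1, 1],
             "hsa-mir-m": [1, 1, 1, 1, 1, 1, 9, 9, 9, 9, 9, 9]},
            6, 6,
        )
        result = identify(ds)
        table = result.table.set_index("mirna")
        assert table.loc["hsa-mir-f", "direction"] == "FB"
        assert table.loc["hsa-mir-m", "direction"] == "MB"
        assert result.fb == {"hsa-mir-f"} and result.mb == {"hsa-mir-m"}

    def test_single_sex_dataset_skipped(self, caplog):
        import logging

        ds = _dataset({"hsa-mir-1": [1, 2, 3, 4]}, 4, 0)
        with caplog.at_level(logging.WARNING, logger="sexbias.biasid"):
            result = identify(ds)
        assert result.table.empty
        assert any("skipped" in r.message for r in caplog.records)

    def test_alpha_monotonicity(self):
        cfg = SynthConfig(n_mirnas=300, n_female=15, n_male=15, frac_biased=0.2, seed=8)
        ds, _ = generate_expression_dataset(cfg)
        flagged = [len(identify(ds, alpha=a).table) for a in (0.1, 0.05, 0.01, 0.001)]
        assert flagged == sorted(flagged, reverse=True)


class TestMerge:
    def test_single_dataset_identity(self):
        result = _result("GSE34608", fb=["hsa-mir-1"], mb=["hsa-mir-2"])
        catalog = merge([result], {"GSE34608": "Infectious"})
        assert catalog.fb("Infectious") == {"hsa-mir-1"}
        assert catalog.mb("Infectious") == {"hsa-mir-2"}

    def test_conflict_excluded_within_group(self):
        r1 = _result("A", fb=["hsa-mir-x", "hsa-mir-1"])
        r2 = _result("B", mb=["hsa-mir-x", "hsa-mir-2"])
        catalog = merge([r1, r2], {"A": "G", "B": "G"})
        assert catalog.excluded_conflicts["G"] == {"hsa-mir-x"}
        assert catalog.fb("G") == {"hsa-mir-1"} and catalog.mb("G") == {"hsa-mir-2"}

    def test_cross_group_conflict_retained_in_group_scope(self):
        r1 = _result("A", fb=["hsa-mir-x"])
        r2 = _result("B", mb=["hsa-mir-x"])
        catalog = merge([r1, r2], {"A": "Infectious", "B": "Neoplasms"})
        assert catalog.fb("Infectious") == {"hsa-mir-x"}
        assert catalog.mb("Neoplasms") == {"hsa-mir-x"}

    def test_global_scope_excludes_cross_group_conflicts(self):
        r1 = _result("A", fb=["hsa-mir-x"])
        r2 = _result("B", mb=["hsa-mir-x"])
        catalog = merge([r1, r2], {"A": "Infectious", "B": "Neoplasms"}, scope="global")
        assert catalog.fb("Infectious") == set()
        assert catalog.mb("Neoplasms") == set()
        assert catalog.excluded_conflicts["Infectious"] == {"hsa-mir-x"}

    def test_order_independent(self):
        results = [
            _result("A", fb=["hsa-mir-1", "hsa-mir-2"]),
            _result("B", mb=["hsa-mir-2"]),
            _result("C", fb=["hsa-mir-3"], mb=["hsa-mir-4"]),
        ]
        gmap = {"A": "G1", "B": "G1", "C": "G2"}
        forward = merge(results, gmap)
        backward = merge(results[::-1], gmap)
        assert forward.groups == backward.groups
        assert forward.excluded_conflicts == backward.excluded_conflicts

    def test_pairwise_disjoint_invariant(self):
        results = [
            _result("A", fb=["hsa-mir-1", "hsa-mir-2"], mb=["hsa-mir-3"]),
            _result("B", fb=["hsa-mir-3"], mb=["hsa-mir-2"]),
        ]
        catalog = merge(results, {"A": "G", "B": "G"})
        fb, mb, ex = catalog.fb("G"), catalog.mb("G"), catalog.excluded_conflicts["G"]
        assert not (fb & mb) and not (fb & ex) and not (mb & ex)

    def test_unmapped_dataset_is_error(self):
        with pytest.raises(ValueError, match="missing from group map"):
            merge([_result("A", fb=["hsa-mir-1"])], {})


class TestOverlapStats:
    def test_disjoint_groups(self):
        catalog = BiasCatalog(
            groups={
                "G1": {"FB": {"a", "b"}, "MB": set()},
                "G2": {"FB": {"c"}, "MB": {"d"}},
            }
        )
        stats = overlap_stats(catalog)
        assert stats["pct_group_unique"] == 100.00
        assert stats["n_total_union"] == 4

    def test_identical_groups(self):
        members = {f"m{i}" for i in range(5)}
        catalog = BiasCatalog(
            groups={"G1": {"FB": members, "MB": set()}, "G2": {"FB": members, "MB": set()}}
        )
        stats = overlap_stats(catalog)
        assert stats["n_total_union"] == 5 and stats["pct_group_unique"] == 0.00
        assert stats["pairwise_overlap"].loc["G1", "G2"] == 5

    def test_empty_catalog(self):
        stats = overlap_stats(BiasCatalog(groups={}))
        assert stats["n_total_union"] == 0 and stats["pct_group_unique"] == 0.0


class TestCompareWithBaseline:
    def test_percentages(self):
        d = {f"m{i}" for i in range(1006)}
        b = set(list(d)[:6])
        assert compare_with_baseline(d, b)["pct"] == 0.60
        d2 = {f"m{i}" for i in range(387)}
        assert compare_with_baseline(d2, set(list(d2)[:2]))["pct"] == 0.52

    def test_identical_sets(self):
        s = {"hsa-mir-1", "hsa-mir-2"}
        assert compare_with_baseline(s, s)["pct"] == 100.00

    def test_empty_disease_set(self):
        with pytest.raises(ValueError, match="empty"):
            compare_with_baseline(set(), {"x"})


class TestGroupAssignment:
    @pytest.mark.parametrize(
        "dataset,expected",
        [("GSE34608", "Infectious"), ("GSE41223", "Endocrine diseases"), ("GSE137140", "Neoplasms")],
    )
    def test_default_disease_groups(self, dataset, expected):
        assert assign_group(dataset) == expected

    @pytest.mark.parametrize(
        "dataset,expected",
        [("GSE34608", "peripheral_blood"), ("GSE25631", "brain"), ("GSE41223", "other")],
    )
    def test_default_tissue_classes(self, dataset, expected):
        assert assign_tissue_class(dataset) == expected

    def test_unknown_dataset_lists_known(self):
        with pytest.raises(KeyError, match="GSE34608"):
            assign_group("GSE999999")

    def test_config_override(self):
        assert assign_group("MY1", {"MY1": "Injury"}) == "Injury"
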