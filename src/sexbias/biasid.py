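"""Sex-biased miRNA identification and cross-dataset merging.

Per dataset, each miRNA's female and male sample values are compared with
a two-sided Wilcoxon rank-sum test; miRNAs with p below the threshold
(0.05 by default, no fold-change filter and no multiple-testing
correction, which is a deliberate choice to retain enough miRNAs for the
downstream global analyses) are called female-biased (FBmiR) when the
female median is higher, male-biased (MBmiR) when lower.

Calls are merged across datasets within disease groups: the per-group FB
set is the union of FB calls, likewise MB; any miRNA called in both
directions is a conflict and is excluded from the catalog.  Conflict
scope is per disease group by default (so cross-group overlaps remain
computable), with a global mode available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexbias.formats import ExpressionDataset
from sexbias.stats_core import ranksum

logger = logging.getLogger(__name__)

__all__ = [
    "SexBiasResult",
    "BiasCatalog",
    "identify",
    "merge",
    "overlap_stats",
    "compare_with_baseline",
    "assign_group",
    "assign_tissue_class",
    "DATASET_DISEASE_GROUP",
    "DATASET_TISSUE_CLASS",
]

#: Default dataset -> disease-group mapping (ICD-11-derived categories)
#: for the 24 GEO series the analysis was designed around.
DATASET_DISEASE_GROUP: dict[str, str] = {
    "GSE34608": "Infectious",
    "GSE134358": "Infectious",
    "GSE42657": "Neoplasms",
    "GSE25631": "Neoplasms",
    "GSE142699": "Neoplasms",
    "GSE39040": "Neoplasms",
    "GSE39052": "Neoplasms",
    "GSE124678": "Neoplasms",
    "GSE126093": "Neoplasms",
    "GSE68204": "Neoplasms",
    "GSE75283": "Neoplasms",
    "GSE76903": "Neoplasms",
    "GSE137140": "Neoplasms",
    "GSE102286": "Neoplasms",
    "GSE155209": "Neoplasms",
    "GSE145259": "Neoplasms",
    "GSE41223": "Endocrine diseases",
    "GSE167559": "Mental disorders",
    "GSE199759": "Epilepsy",
    "GSE205661": "Epilepsy",
    "GSE160308": "Retinopathy",
    "GSE137995": "Developmental anomalies",
    "GSE215940": "Developmental anomalies",
    "GSE174661": "Injury",
}

#: Default dataset -> tissue-class mapping (sample source of each series).
DATASET_TISSUE_CLASS: dict[str, str] = {
    "GSE34608": "peripheral_blood",
    "GSE134358": "peripheral_blood",
    "GSE137140": "peripheral_blood",
    "GSE142699": "peripheral_blood",
    "GSE167559": "peripheral_blood",
    "GSE215940": "peripheral_blood",
    "GSE25631": "brain",
    "GSE42657": "brain",
    "GSE199759": "brain",
    "GSE205661": "brain",
    "GSE39040": "neoplasms",
    "GSE39052": "neoplasms",
    "GSE68204": "neoplasms",
    "GSE75283": "neoplasms",
    "GSE76903": "neoplasms",
    "GSE102286": "neoplasms",
    "GSE124678": "neoplasms",
    "GSE126093": "neoplasms",
    "GSE145259": "neoplasms",
    "GSE155209": "neoplasms",
    "GSE41223": "other",
    "GSE137995": "other",
    "GSE160308": "other",
    "GSE174661": "other",
}


@dataclass
class SexBiasResult:
    """Significant sex-biased calls for one dataset.

    ``table`` has one row per flagged miRNA with columns ``mirna``,
    ``p_two_sided``, ``direction`` (FB/MB), ``median_female``,
    ``median_male``.
    """

    dataset_id: str
    table: pd.DataFrame
    n_tested: int = 0
    n_dropped_ties: int = 0

    @property
    def fb(self) -> set[str]:
        return set(self.table.loc[self.table["direction"] == "FB", "mirna"])

    @property
    def mb(self) -> set[str]:
        return set(self.table.loc[self.table["direction"] == "MB", "mirna"])


@dataclass
class BiasCatalog:
    """Merged, conflict-free FBmiR/MBmiR sets per disease group.

    ``groups`` maps disease group -> {"FB": set, "MB": set}.  Conflicting
    miRNAs are recorded in ``excluded_conflicts`` per group and appear in
    neither set.  OmiR for a group is everything else in a given
    annotation universe.
    """

    groups: dict[str, dict[str, set[str]]]
    excluded_conflicts: dict[str, set[str]] = field(default_factory=dict)
    scope: str = "group"

    def fb(self, group: str) -> set[str]:
        return self.groups[group]["FB"]

    def mb(self, group: str) -> set[str]:
        return self.groups[group]["MB"]

    def omir(self, group: str, universe: set[str]) -> set[str]:
        return set(universe) - self.fb(group) - self.mb(group)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups)


def identify(dataset: ExpressionDataset, alpha: float = 0.05) -> SexBiasResult:
    """Call sex-biased miRNAs in one dataset at threshold ``alpha``.

    Per miRNA, non-null female values are rank-sum tested against male
    values; p < alpha flags the miRNA, with direction decided by the
    sex with the higher median.  A flagged miRNA whose medians tie is
    dropped with a warning; all-constant rows get p = 1 and are never
    flagged.  Datasets with zero samples of either sex yield an empty
    result with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    female_cols = dataset.sex_columns("F")
    male_cols = dataset.sex_columns("M")
    empty = pd.DataFrame(
        columns=["mirna", "p_two_sided", "direction", "median_female", "median_male"]
    )
    if not female_cols or not male_cols:
        logger.warning(
            "%s: skipped (%d female, %d male samples)",
            dataset.dataset_id,
            len(female_cols),
            len(male_cols),
        )
        return SexBiasResult(dataset_id=dataset.dataset_id, table=empty, n_tested=0)

    rows = []
    n_dropped_ties = 0
    fmat = dataset.matrix[female_cols]
    mmat = dataset.matrix[male_cols]
    for mirna in dataset.matrix.index:
        fv = fmat.loc[mirna].dropna().to_numpy(dtype=float)
        mv = mmat.loc[mirna].dropna().to_numpy(dtype=float)
        if fv.size == 0 or mv.size == 0:
            continue
        res = ranksum(fv, mv)
        if res.p_two_sided >= alpha:
            continue
        med_f, med_m = float(np.median(fv)), float(np.median(mv))
        if med_f == med_m:
            n_dropped_ties += 1
            logger.warning("%s: %s significant but medians tie; dropped", dataset.dataset_id, mirna)
            continue
        rows.append(
            {
                "mirna": mirna,
                "p_two_sided": res.p_two_sided,
                "direction": "FB" if med_f > med_m else "MB",
                "median_female": med_f,
                "median_male": med_m,
            }
        )
    table = pd.DataFrame(rows, columns=empty.columns) if rows else empty
    return SexBiasResult(
        dataset_id=dataset.dataset_id,
        table=table,
        n_tested=len(dataset.matrix),
        n_dropped_ties=n_dropped_ties,
    )


def merge(
    results: list[SexBiasResult],
    group_map: dict[str, str],
    scope: str = "group",
) -> BiasCatalog:
    """Merge per-dataset calls into a conflict-free catalog.

    Within each disease group the FB (MB) set is the union over datasets;
    a miRNA in both unions is a conflict and is moved to that group's
    ``excluded_conflicts``.  With ``scope="global"`` a miRNA whose
    direction conflicts across *any* pair of groups is excluded from the
    whole catalog.  Merging is order-independent.
    """
    if scope not in ("group", "global"):
        raise ValueError(f"scope must be 'group' or 'global', got {scope!r}")
    unmapped = [r.dataset_id for r in results if r.dataset_id not in group_map]
    if unmapped:
        raise ValueError(f"datasets missing from group map: {unmapped}")

    fb_by_group: dict[str, set[str]] = {}
    mb_by_group: dict[str, set[str]] = {}
    for result in results:
        group = group_map[result.dataset_id]
        fb_by_group.setdefault(group, set()).update(result.fb)
        mb_by_group.setdefault(group, set()).update(result.mb)

    groups: dict[str, dict[str, set[str]]] = {}
    excluded: dict[str, set[str]] = {}
    for group in set(fb_by_group) | set(mb_by_group):
        fb = fb_by_group.get(group, set())
        mb = mb_by_group.get(group, set())
        conflicts = fb & mb
        groups[group] = {"FB": fb - conflicts, "MB": mb - conflicts}
        excluded[group] = conflicts

    if scope == "global":
        all_fb = set().union(*(g["FB"] for g in groups.values())) if groups else set()
        all_mb = set().union(*(g["MB"] for g in groups.values())) if groups else set()
        cross = all_fb & all_mb
        for group in groups:
            groups[group]["FB"] -= cross
            groups[group]["MB"] -= cross
            excluded[group] |= cross

    return BiasCatalog(groups=groups, excluded_conflicts=excluded, scope=scope)


def overlap_stats(catalog: BiasCatalog) -> dict:
    """Cross-group overlap summary of the merged catalog.

    A miRNA is group-unique when it appears (as FB or MB) in exactly one
    disease group; the headline percentage is 100 * unique / union size,
    rounded to two decimals.  Also returns the pairwise group-overlap
    count matrix.
    """
    per_group = {g: catalog.fb(g) | catalog.mb(g) for g in catalog.groups}
    if not per_group:
        return {
            "n_total_union": 0,
            "n_group_unique": 0,
            "pct_group_unique": 0.0,
            "pairwise_overlap": pd.DataFrame(),
        }
    union: set[str] = set().union(*per_group.values())
    membership = {m: sum(m in s for s in per_group.values()) for m in union}
    n_unique = sum(1 for c in membership.values() if c == 1)
    pct = round(100.0 * n_unique / len(union), 2) if union else 0.0
    names = sorted(per_group)
    matrix = pd.DataFrame(
        [[len(per_group[a] & per_group[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return {
        "n_total_union": len(union),
        "n_group_unique": n_unique,
        "pct_group_unique": pct,
        "pairwise_overlap": matrix,
    }


def compare_with_baseline(disease_precursors: set, baseline_precursors: set) -> dict:
    """Overlap of disease-state calls with a healthy-state baseline,
    both at precursor level.  Percentage is relative to the disease set,
    rounded to two decimals."""
    disease_precursors = set(disease_precursors)
    if not disease_precursors:
        raise ValueError("disease precursor set is empty")
    overlap = disease_precursors & set(baseline_precursors)
    n_disease = len(disease_precursors)
    return {
        "n_overlap": len(overlap),
        "n_disease": n_disease,
        "pct": round(100.0 * len(overlap) / n_disease, 2),
    }


def _lookup(dataset_id: str, mapping: dict[str, str], what: str) -> str:
    if dataset_id not in mapping:
        raise KeyError(
            f"unknown dataset {dataset_id!r} for {what}; known: {sorted(mapping)}"
        )
    return mapping[dataset_id]


def assign_group(dataset_id: str, config: dict[str, str] | None = None) -> str:
    """Disease group for a dataset; ships the default 24-series mapping."""
    return _lookup(dataset_id, config or DATASET_DISEASE_GROUP, "disease group")


def assign_tissue_class(dataset_id: str, config: dict[str, str] | None = None) -> str:
    """Tissue class for a dataset; ships the default 24-series mapping."""
    return _lookup(dataset_id, config or DATASET_TISSUE_CLASS, "tissue class")
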