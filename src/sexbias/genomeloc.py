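"""Chromosomal distribution and genomic clustering of miRNA sets.

miRNA genes are not randomly placed; sex-biased sets tend to aggregate
in genomic clusters.  The clustering statistic here is the distribution
of intrachromosomal start-to-start distances over all same-chromosome
pairs within a set, compared between sets (e.g. FBmiR vs OmiR) with the
rank-sum test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from sexbias.formats import MiRNAAnnotation
from sexbias.stats_core import RankSumResult, ranksum

__all__ = [
    "chromosome_counts",
    "autosome_fraction",
    "intrachrom_distances",
    "compare_distance_distributions",
]

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def chromosome_counts(mirna_set, annotation: MiRNAAnnotation) -> pd.Series:
    """Per-chromosome member counts, zero-filled over all annotated
    chromosomes; set members absent from the annotation are skipped."""
    all_chroms = sorted(annotation.table["chromosome"].unique())
    counts = pd.Series(0, index=pd.Index(all_chroms, name="chromosome"), dtype=int)
    sub = annotation.subset(mirna_set)
    observed = sub["chromosome"].value_counts()
    counts.loc[observed.index] += observed.astype(int)
    return counts


def autosome_fraction(mirna_set, annotation: MiRNAAnnotation) -> float:
    """Fraction of annotated set members on autosomes (not chrX/chrY)."""
    sub = annotation.subset(mirna_set)
    if sub.empty:
        raise ValueError("autosome_fraction of an empty (or unannotated) set")
    on_autosome = (~sub["chromosome"].isin(_SEX_CHROMS)).sum()
    return float(on_autosome) / len(sub)


def intrachrom_distances(mirna_set, annotation: MiRNAAnnotation, gap: bool = False) -> np.ndarray:
    """Start-to-start bp distances over all same-chromosome member pairs.

    Every unordered pair of distinct set members sharing a chromosome
    contributes ``|start_i - start_j|``; cross-chromosome pairs
    contribute nothing.  With ``gap=True`` the distance is instead the
    gap between the two precursor intervals (0 when they overlap).
    """
    sub = annotation.subset(mirna_set)
    distances: list[float] = []
    for _, chrom_df in sub.groupby("chromosome", sort=True):
        rows = list(chrom_df.itertuples())
        for a, b in itertools.combinations(rows, 2):
            if gap:
                d = max(a.start, b.start) - min(a.end, b.end)
                distances.append(float(max(d, 0)))
            else:
                distances.append(float(abs(a.start - b.start)))
    return np.asarray(distances, dtype=float)


def compare_distance_distributions(
    set_a, set_b, annotation: MiRNAAnnotation, gap: bool = False
) -> RankSumResult:
    """Rank-sum comparison of two sets' intrachromosomal distance
    distributions; an empty distance vector is an error naming the set."""
    da = intrachrom_distances(set_a, annotation, gap=gap)
    db = intrachrom_distances(set_b, annotation, gap=gap)
    if da.size == 0:
        raise ValueError("first set has no same-chromosome pairs")
    if db.size == 0:
        raise ValueError("second set has no same-chromosome pairs")
    return ranksum(da, db)
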