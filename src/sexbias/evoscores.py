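"""Evolutionary conservation, tissue specificity, and disease spectrum width.

Conservation is summarized two ways: a five-level group label (G1
human-specific through G5 present in distal species, the most conserved),
and the number of distinct species carrying members of a miRNA's family.
Tissue specificity is the tau index in [0, 1] (0 uniform, 1 single
tissue); disease spectrum width (DSW) measures how many distinct diseases
a miRNA is linked to in a curated association table.  Each score is
compared between FBmiR, MBmiR and the OmiR background with the rank-sum
test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sexbias.biasid import BiasCatalog
from sexbias.formats import CONSERVATION_GROUPS, AssociationTable, MiRNAAnnotation
from sexbias.names import normalize_name
from sexbias.stats_core import ranksum

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CLADE_RANK",
    "classify_conservation",
    "conservation_proportions",
    "family_species_count",
    "family_species_count_map",
    "dsw",
    "compare_scores",
    "compute_tsi",
]

#: Species prefix -> clade rank (1 human, 2 primate, 3 mammal,
#: 4 vertebrate, 5 more distal).  Editable via config; unknown prefixes
#: are treated as distal with a warning.
DEFAULT_CLADE_RANK: dict[str, int] = {
    "hsa": 1,
    # primates
    "ptr": 2, "ggo": 2, "ppy": 2, "mml": 2, "ppa": 2, "sla": 2, "age": 2,
    "mne": 2, "lla": 2, "cja": 2, "sbo": 2,
    # non-primate mammals
    "mmu": 3, "rno": 3, "bta": 3, "cfa": 3, "ssc": 3, "ocu": 3, "eca": 3,
    "oar": 3, "chi": 3, "mdo": 3, "sha": 3, "oan": 3, "ago": 3, "cgr": 3,
    # non-mammal vertebrates
    "gga": 4, "dre": 4, "xtr": 4, "xla": 4, "aca": 4, "tgu": 4, "ola": 4,
    "tni": 4, "fru": 4, "ssa": 4, "gmo": 4,
    # distal species
    "cel": 5, "cbr": 5, "dme": 5, "dps": 5, "cin": 5, "csa": 5, "sma": 5,
    "bfl": 5, "spu": 5, "aga": 5, "ame": 5, "bmo": 5, "lgi": 5, "nve": 5,
}


def classify_conservation(species_prefixes, clade_config: dict[str, int] | None = None) -> str:
    """Conservation group (G1..G5) from the species present in a family.

    The group is set by the deepest clade represented: human-only -> G1,
    up to distal species -> G5.  An unknown prefix is logged and treated
    as distal.
    """
    clade = clade_config or DEFAULT_CLADE_RANK
    prefixes = set(species_prefixes)
    if not prefixes:
        raise ValueError("classify_conservation needs at least one species prefix")
    deepest = 1
    for prefix in prefixes:
        rank = clade.get(prefix)
        if rank is None:
            logger.warning("unknown species prefix %r; treated as distal", prefix)
            rank = 5
        deepest = max(deepest, rank)
    return CONSERVATION_GROUPS[deepest - 1]


def conservation_proportions(
    catalog: BiasCatalog, annotation: MiRNAAnnotation
) -> pd.DataFrame:
    """Per-group, per-set (FBmiR/MBmiR/OmiR) conservation-group shares.

    Rows are indexed by (disease_group, set) and hold the G1..G5
    proportions among annotated members; each row sums to 1.  Empty sets
    are an error.
    """
    rows = {}
    cons = annotation.table["conservation_group"]
    for group in catalog.group_names:
        sets = {
            "FBmiR": catalog.fb(group),
            "MBmiR": catalog.mb(group),
            "OmiR": catalog.omir(group, annotation.universe),
        }
        for set_name, members in sets.items():
            annotated = [m for m in members if m in cons.index]
            if not annotated:
                raise ValueError(f"{group}/{set_name}: no annotated members")
            shares = cons.loc[annotated].value_counts(normalize=True)
            rows[(group, set_name)] = [float(shares.get(g, 0.0)) for g in CONSERVATION_GROUPS]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(CONSERVATION_GROUPS))
    out.index = pd.MultiIndex.from_tuples(out.index, names=["disease_group", "set"])
    return out


def species_prefix(member: str) -> str:
    """First hyphen-delimited token of a member name (``hsa-mir-17`` -> ``hsa``)."""
    return member.split("-", 1)[0]


def family_species_count(mirna: str, family_map: dict[str, list[str]]) -> int:
    """Number of distinct species carrying members of the miRNA's family.

    ``family_map`` maps family accession -> member names (the miFam
    reader's output).  A miRNA belonging to no family counts as 1 (it
    exists in human); excluding family-less miRNAs would silently shrink
    the comparison sets.
    """
    name = normalize_name(mirna)
    for members in family_map.values():
        if name in members:
            return len({species_prefix(m) for m in members})
    return 1


def family_species_count_map(
    family_map: dict[str, list[str]], universe
) -> dict[str, int]:
    """Vector form of :func:`family_species_count` over a miRNA universe."""
    member_counts: dict[str, int] = {}
    for members in family_map.values():
        n_species = len({species_prefix(m) for m in members})
        for m in members:
            member_counts[m] = n_species
    return {normalize_name(m): member_counts.get(normalize_name(m), 1) for m in universe}


def dsw(mirna: str, associations: AssociationTable, normalizer: str = "ratio") -> float:
    """Disease spectrum width of a miRNA.

    With the default ``"ratio"`` normalizer this is the number of
    distinct diseases linked to the miRNA divided by the size of the
    association table's disease universe (so DSW is in [0, 1]); with
    ``"count"`` it is the raw disease count.  A miRNA absent from the
    table scores 0.  Every comparison downstream depends only on the
    score being monotone in the disease count, so either normalizer
    yields identical rank-sum results.
    """
    if normalizer not in ("ratio", "count"):
        raise ValueError(f"normalizer must be 'ratio' or 'count', got {normalizer!r}")
    if not associations.disease_universe:
        raise ValueError("association table has an empty disease universe")
    n = len(associations.diseases_of(mirna))
    if normalizer == "count":
        return float(n)
    return n / len(associations.disease_universe)


_COMPARISONS = (("FBmiR", "OmiR"), ("MBmiR", "OmiR"), ("FBmiR", "MBmiR"))


def compare_scores(
    catalog: BiasCatalog,
    score_map: dict[str, float],
    annotation: MiRNAAnnotation,
    score_name: str = "score",
) -> pd.DataFrame:
    """Rank-sum comparisons of a per-miRNA score between FBmiR, MBmiR and
    OmiR within each disease group.

    miRNAs without a score are excluded (counted in the log).  Returns
    one row per (disease_group, comparison) with set sizes, medians, the
    U statistic and the two-sided p-value.
    """
    score_map = {normalize_name(m): float(v) for m, v in score_map.items()}
    rows = []
    for group in catalog.group_names:
        sets = {
            "FBmiR": catalog.fb(group),
            "MBmiR": catalog.mb(group),
            "OmiR": catalog.omir(group, annotation.universe),
        }
        vectors = {}
        for set_name, members in sets.items():
            scored = [score_map[m] for m in members if m in score_map]
            n_missing = len(members) - len(scored)
            if n_missing:
                logger.info(
                    "%s/%s: %d of %d members lack a %s score",
                    group, set_name, n_missing, len(members), score_name,
                )
            vectors[set_name] = np.asarray(scored, dtype=float)
        for name_a, name_b in _COMPARISONS:
            va, vb = vectors[name_a], vectors[name_b]
            if va.size == 0 or vb.size == 0:
                raise ValueError(f"{group}: empty score vector for {name_a} vs {name_b}")
            res = ranksum(va, vb)
            rows.append(
                {
                    "disease_group": group,
                    "score": score_name,
                    "comparison": f"{name_a} vs {name_b}",
                    "n_a": int(va.size),
                    "n_b": int(vb.size),
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "u_statistic": res.u_statistic,
                    "p_two_sided": res.p_two_sided,
                }
            )
    return pd.DataFrame(rows)


def compute_tsi(expression_by_tissue) -> float:
    """Tissue specificity index tau of one miRNA's cross-tissue profile.

    ``tau = sum_i (1 - x_i / x_max) / (N - 1)`` over N >= 2 tissues with
    non-negative expression; 0 for a uniform profile, 1 for single-tissue
    expression.  Invariant under positive rescaling.
    """
    x = np.asarray(expression_by_tissue, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D profile over >= 2 tissues")
    if np.any(x < 0) or not np.isfinite(x).all():
        raise ValueError("tau needs finite, non-negative expression values")
    x_max = x.max()
    if x_max == 0:
        raise ValueError("tau is undefined for an all-zero profile")
    return float(np.sum(1.0 - x / x_max) / (x.size - 1))
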