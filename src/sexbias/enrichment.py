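"""miRNA-set over-representation analysis.

A query miRNA set (e.g. the FBmiR of one disease group) is tested
against named category sets (function, disease, transcription-factor
target collections) with the hypergeometric upper tail, then BH-adjusted
within each category class.  This replaces a web-service call with a
transparent over-representation core.

A weighted variant scores each category by the summed per-miRNA weights
of its overlap with the query and calibrates significance against
random same-size queries drawn from the universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sexbias.formats import CategorySetCollection
from sexbias.names import normalize_name
from sexbias.stats_core import bh_fdr, hypergeom_upper

__all__ = ["enrich", "enrich_weighted"]

_COLUMNS = [
    "category_class",
    "category_name",
    "overlap_count",
    "set_size",
    "query_size",
    "universe_size",
    "p_upper",
    "q_bh",
    "overlapping_mirnas",
]


def _resolve_universe(categories: CategorySetCollection, universe) -> set[str]:
    if universe is None:
        return categories.member_universe
    return {normalize_name(m) for m in universe}


def enrich(
    query,
    categories: CategorySetCollection,
    universe=None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each category.

    The universe defaults to all miRNAs appearing in the category
    collection; category sets and the query are intersected with it
    before testing.  Per category with non-empty universe intersection,
    ``p = P(X >= k)`` for Hypergeometric(N=|universe|, K=|set|,
    n=|query|); BH q-values are computed over all tested categories of
    the class.  Rows are sorted by p.
    """
    universe_set = _resolve_universe(categories, universe)
    query_set = {normalize_name(m) for m in query} & universe_set
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")

    rows = []
    for name in sorted(categories.sets):
        members = categories.sets[name] & universe_set
        if not members:
            continue
        overlap = sorted(query_set & members)
        p = hypergeom_upper(len(overlap), len(members), len(query_set), len(universe_set))
        rows.append(
            {
                "category_class": categories.class_name,
                "category_name": name,
                "overlap_count": len(overlap),
                "set_size": len(members),
                "query_size": len(query_set),
                "universe_size": len(universe_set),
                "p_upper": p,
                "overlapping_mirnas": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["q_bh"] = bh_fdr(table["p_upper"].to_numpy())
    table = table.sort_values(["p_upper", "category_name"], kind="mergesort").reset_index(drop=True)
    return table[_COLUMNS]


def enrich_weighted(
    query_weights: dict[str, float],
    categories: CategorySetCollection,
    universe=None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weight-sum over-representation with a permutation null.

    ``query_weights`` maps query miRNAs to positive weights (e.g. the
    number of datasets supporting each call).  Each category scores the
    summed weights of its overlap with the query; the p-value is the
    add-one-corrected fraction of ``n_permutations`` random same-size
    queries from the universe whose score reaches the observed one.
    miRNAs outside the query carry weight 1 in null draws unless listed
    in ``query_weights``.  With all weights equal the ranking reduces to
    the unweighted overlap-count ranking.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    weights = {normalize_name(m): float(w) for m, w in query_weights.items()}
    if any(w <= 0 for w in weights.values()):
        raise ValueError("weights must be positive")
    universe_set = _resolve_universe(categories, universe)
    query_set = set(weights) & universe_set
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")

    universe_list = sorted(universe_set)
    w_universe = np.asarray([weights.get(m, 1.0) for m in universe_list])
    index_of = {m: i for i, m in enumerate(universe_list)}
    rng = np.random.default_rng(seed)

    cat_names = [n for n in sorted(categories.sets) if categories.sets[n] & universe_set]
    cat_masks = np.zeros((len(cat_names), len(universe_list)), dtype=bool)
    for ci, name in enumerate(cat_names):
        for m in categories.sets[name] & universe_set:
            cat_masks[ci, index_of[m]] = True

    q_idx = np.asarray([index_of[m] for m in sorted(query_set)])
    observed = np.array([w_universe[q_idx[cat_masks[ci, q_idx]]].sum() for ci in range(len(cat_names))])

    exceed = np.zeros(len(cat_names), dtype=int)
    for _ in range(n_permutations):
        perm_idx = rng.choice(len(universe_list), size=len(q_idx), replace=False)
        scores = np.array(
            [w_universe[perm_idx[cat_masks[ci, perm_idx]]].sum() for ci in range(len(cat_names))]
        )
        exceed += scores >= observed - 1e-12
    p_perm = (exceed + 1) / (n_permutations + 1)

    rows = []
    for ci, name in enumerate(cat_names):
        members = categories.sets[name] & universe_set
        overlap = sorted(query_set & members)
        rows.append(
            {
                "category_class": categories.class_name,
                "category_name": name,
                "overlap_count": len(overlap),
                "set_size": len(members),
                "query_size": len(query_set),
                "universe_size": len(universe_set),
                "weight_score": float(observed[ci]),
                "p_perm": float(p_perm[ci]),
                "overlapping_mirnas": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["q_bh"] = bh_fdr(table["p_perm"].to_numpy())
    return table.sort_values(["p_perm", "category_name"], kind="mergesort").reset_index(drop=True)
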