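# Methods

## Problem and scope

The package detects miRNAs whose expression differs between female and
male patients *within* a disease state and characterizes the resulting
female-biased (FBmiR) and male-biased (MBmiR) catalogs against the
background of all other annotated miRNAs (OmiR). It operates strictly
downstream of normalization: inputs are normalized miRNA × sample
matrices, and no cross-dataset expression comparison is ever made —
datasets are only combined at the level of called miRNA sets.

## Identification model

Per dataset and miRNA, female values are compared with male values by a
two-sided Wilcoxon rank-sum test; calls use p < α (default 0.05).

- **Exact vs approximate.** With combined sample size n₁+n₂ ≤ 16 the
  permutation distribution of the rank sum (midranks, so ties are
  respected) is enumerated exactly via a subset-sum dynamic program —
  at most C(16,8) = 12 870 arrangements. This matters because real
  series in this domain can have groups as small as 1 vs 8, where the
  normal approximation misbehaves. Above the cutoff, a tie-corrected
  normal approximation with 0.5 continuity correction is used; it
  matches scipy's asymptotic Mann–Whitney to ~1e-9 relative error
  (cross-checked in tests). Two-sided p doubles the smaller tail,
  capped at 1.
- **Direction by median.** "Higher expression" is judged by the sample
  median, consistent with the rank-based test; a significant miRNA
  whose medians tie is dropped with a warning (direction would be
  arbitrary). All-constant rows get p = 1.
- **No fold-change filter, no FDR in identification.** The intended
  product is a broad catalog for global set-level analyses; an FDR
  routine exists in `stats_core` and is applied only to enrichment
  tables. Significance of identification calls should therefore be
  read as exploratory.

## Merging and conflict exclusion

Within each disease group, FB (MB) is the union of FB (MB) calls over
the group's datasets; any miRNA in both unions is a conflict, removed
from both sets and recorded. Conflict scope is **per disease group** by
default: a miRNA may legitimately be female-biased in infections and
male-biased in neoplasms, and per-group scoping keeps cross-group
overlap statistics meaningful. A `global` scope (exclude everywhere on
any cross-group conflict) is available. Merging is order-independent,
and datasets that yield zero calls are legitimate, not errors.

## Characterization statistics

- **Chromosome distribution**: per-chromosome counts (zero-filled) and
  the autosome fraction (share of set members not on chrX/chrY).
- **Genomic clustering**: for each set, all same-chromosome unordered
  pairs contribute |startᵢ − startⱼ| (start-to-start is well-defined
  even for overlapping precursors; an interval-gap distance is
  available behind a flag, strand ignored). Distance distributions of
  two sets are compared with the rank-sum test, within-set pairs per
  group. Pair counts follow Σ_chrom C(n_chrom, 2).
- **Conservation**: each precursor carries a group label G1 (human-
  specific) → G5 (present in distal species, the most conserved). A
  family's group is the deepest clade among its members' species
  prefixes (hsa=1, primates=2, mammals=3, vertebrates=4, distal=5; the
  prefix→rank table is editable config, unknown prefixes count as
  distal with a warning). Family species counts come from a
  miFam-dialect file; a miRNA with no family counts as 1 species
  (itself) rather than being dropped, which would silently shrink
  comparison sets.
- **Tissue specificity**: consumed as a provided per-miRNA score table
  in [0,1]; a tau implementation (Σ(1 − xᵢ/x_max)/(N−1)) is included
  for synthetic end-to-end use. Tau is invariant under positive
  rescaling, undefined for all-zero profiles.
- **Disease spectrum width**: DSW(m) = |diseases linked to m| /
  |disease universe| by default. The reference definition of this
  score lives outside this codebase; every comparison made here
  depends only on a score monotone in the disease count, so the
  normalizer (ratio vs raw count) is configurable and does not change
  any rank-sum result. Absent miRNAs score 0; an empty disease
  universe is an error.
- All score comparisons (FB vs O, MB vs O, FB vs MB per group) report
  set sizes, medians, U and two-sided p; miRNAs without a score are
  excluded and counted in the log.

## Enrichment

Over-representation of a query set against named category sets
(function / disease / transcription-factor classes) uses the
hypergeometric upper tail with the universe defaulting to all miRNAs in
the category collection (configurable to the annotation universe), and
BH correction within each class separately, since the three analyses
are reported separately. The weighted variant scores each category by
the summed weights of its query overlap and calibrates against random
same-size queries (add-one-corrected permutation p, default weight 1
for non-query members in null draws); it is a documented stand-in for
weighted set-analysis schemes whose internals are not public, not a
re-implementation of any specific tool, and reduces to the unweighted
ranking when all weights are equal.

## Synthetic data: what it emulates

Expression is Gaussian on a log scale: per-miRNA baseline
N(μ₀=8, τ=2), per-sample noise N(0, σ=1) — the shape of a normalized
log₂ microarray matrix. A planted biased miRNA shifts the favored sex
by `effect_size · σ` (default 1.5), making rank-sum power predictable.
Defaults: 1000 miRNAs, 30+30 samples, 10% biased with 75% of those
female-biased (disease catalogs skew roughly 3:1 female), 7% of miRNAs
on sex chromosomes (so ≈93% autosomal).

The multi-dataset "world" generator additionally plants the qualitative
pattern the analysis is designed to detect: biased miRNAs (female most)
are drawn toward the conserved groups, carry +0.30/+0.15 TSI boosts
(FB/MB over a Beta(2,4) background), have denser disease associations
(0.35/0.20 vs 0.08 over 30 diseases), and autosomal biased miRNAs are
placed in clusters of 3–5 within a 10 kb span (sex-chromosome members
are left in place so the 7% share survives clustering). Family files
are generated consistently with conservation groups: a Gk family
contains at least one species of clade k and none deeper, so
conservation re-derived from the family file agrees with the
annotation.

What the generator does **not** emulate: platform probe IDs, missing
values, batch effects, correlated miRNAs (clustered miRNAs are placed
near each other but expressed independently), non-Gaussian tails, or
realistic disease ontologies. A green end-to-end test therefore
establishes that the pipeline recovers planted monotone structure under
idealized noise — not that any biological claim holds.

## Numerical and interface choices

- Exact-test cutoff n₁+n₂ ≤ 16; doubling-the-smaller-tail two-sided
  convention; variance-zero (all tied) cases return p = 1.
- Duplicate expression rows mapping to one harmonized name are averaged
  (order-independent, scale-preserving); all-null rows are dropped;
  both counts are logged.
- Names are harmonized to miRBase precursor form (lowercase, trimmed).
  Mature→precursor mapping uses Derives_from links from the GFF3 when
  available, falling back to stripping a -5p/-3p arm suffix with a
  logged warning.
- Coordinates are 1-based inclusive everywhere (miRBase GFF3
  convention).
- All pipeline randomness flows from one seed through named
  substreams, and outputs are byte-identical across reruns of the same
  config (sorted JSON keys, no timestamps).

## Known limitations

- Identification p-values are uncorrected by design; the catalog's
  false-discovery proportion tracks α times the unbiased fraction.
- The rank-sum normal approximation's continuity correction is a
  convention; near the exact cutoff, p-values from the two branches can
  differ by a few percent.
- Per-group conflict scoping means a miRNA can appear with opposite
  directions in different groups; consumers pooling groups should use
  the global scope.
- The weighted enrichment p-value is a Monte-Carlo estimate; its
  resolution is 1/(n_permutations+1).
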