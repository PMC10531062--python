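# sexbias

Identification and characterization of **disease-associated sex-biased
miRNAs** from normalized miRNA expression matrices with per-sample sex
labels.

Many diseases manifest differently in women and men, and miRNAs — short
regulatory noncoding RNAs — are among the molecules whose expression can
differ by sex in the disease state. Given a collection of expression
datasets (miRNA × sample matrices, each sample labelled female/male and
assigned to a disease), this package:

1. **identifies** female-biased (FBmiR) and male-biased (MBmiR) miRNAs
   per dataset with a two-sided Wilcoxon rank-sum test at *p* < 0.05
   (no fold-change filter, no multiple-testing correction — the goal is
   a broad catalog, not a short candidate list);
2. **merges** calls across datasets within disease groups, excluding
   miRNAs with conflicting direction;
3. **characterizes** the resulting FBmiR/MBmiR sets against the OmiR
   background (all other annotated miRNAs): chromosome distribution and
   autosome fraction, intrachromosomal pairwise-distance clustering,
   evolutionary conservation (group labels G1 human-specific … G5
   present in distal species, and family species counts from a
   miFam-style family file), tissue-specificity index (tau), and
   disease spectrum width (DSW = associated diseases / disease
   universe, from an HMDD-style association table);
4. runs **miRNA-set over-representation analysis** (hypergeometric
   upper tail + Benjamini–Hochberg FDR per category class) against
   function / disease / transcription-factor category sets, plus a
   weighted permutation-null variant.

A synthetic-data module generates every input with planted ground truth
(shift direction per miRNA, conservation/TSI/DSW structure, genomic
clusters), so the whole pipeline is testable without downloads.

## Statistical core

For miRNA *i* with female values *x* and male values *y*, the two-sided
rank-sum test uses midranks; for n₁+n₂ ≤ 16 the permutation
distribution of the rank sum is enumerated exactly (several real
datasets have groups as small as 1 vs 8), otherwise a tie-corrected
normal approximation with continuity correction is used. Direction is
assigned by median: FB if median(x) > median(y), MB if smaller.

Over-representation of a query set Q in category C within universe U is
P(X ≥ |Q∩C|) for X ~ Hypergeometric(N=|U|, K=|C∩U|, n=|Q∩U|).

Tissue specificity is tau = Σᵢ (1 − xᵢ/x_max) / (N−1) over N tissues
(0 = uniform, 1 = single-tissue).

## Worked example

Generate a two-group synthetic scenario and run the full pipeline:

```sh
sexbias synth --seed 7 --outdir fixtures/
sexbias run --config fixtures/run.yaml --outdir report/
```

which prints

```
Infectious: 95 FBmiR, 44 MBmiR, 0 conflicts excluded
Neoplasms: 98 FBmiR, 48 MBmiR, 0 conflicts excluded
report written to report
```

i.e. per disease group, the number of female-/male-biased miRNAs in the
merged catalog and how many were dropped for conflicting direction.
`report/` then contains plot-data tables. For instance
`tsi_comparison.tsv` starts

```
disease_group  score  comparison      n_a  n_b  median_a  median_b  p_two_sided
Infectious     tsi    FBmiR vs OmiR   95   861  0.580     0.341     1.3e-18
Infectious     tsi    MBmiR vs OmiR   44   861  0.480     0.341     2.6e-05
Infectious     tsi    FBmiR vs MBmiR  95   44   0.580     0.480     6.1e-03
```

— the planted pattern (female-biased miRNAs more tissue-specific than
the background, male-biased in between) is recovered, with set sizes,
medians and rank-sum p-values. `conservation_proportions.tsv`,
`dsw_comparison.tsv`, `distance_comparison.tsv`,
`chromosome_counts.tsv`, `autosome_fraction.tsv` and `enrichment.tsv`
report the remaining characterizations the same way;
`manifest.json` records seeds, thresholds and per-dataset counts.

Library use mirrors the CLI:

```python
from sexbias import biasid, formats

ds = formats.read_expression("expr.tsv", "meta.tsv", dataset_id="GSE34608")
result = biasid.identify(ds, alpha=0.05)          # per-miRNA calls
catalog = biasid.merge([result], {"GSE34608": biasid.assign_group("GSE34608")})
```

## Acceptance script

`scripts/acceptance.py` regenerates the synthetic world from the given
seed, runs the complete pipeline on it (identification through
enrichment), and writes its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `sexbias.synthdata` — generators for every input, with planted truth
- `sexbias.formats` — readers/writers (expression TSV, miRBase-dialect
  GFF3, miFam-dialect families, association CSV, category-set TSV, TSI TSV)
- `sexbias.names` — name harmonization, mature→precursor mapping
- `sexbias.stats_core` — rank-sum (exact + approximate), hypergeometric
  tail, BH FDR
- `sexbias.biasid` — per-dataset identification, conflict-excluding
  merge, overlap statistics, dataset→group/tissue assignment
- `sexbias.genomeloc` — chromosome counts, autosome fraction,
  intrachromosomal distance statistics
- `sexbias.evoscores` — conservation groups, family species counts,
  tau, DSW, score comparisons
- `sexbias.enrichment` — set over-representation (plain and weighted)
- `sexbias.pipeline` / `sexbias.cli` — orchestration and the `sexbias`
  command

See `docs/methods.md` for the model, parameter choices, and limitations.
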