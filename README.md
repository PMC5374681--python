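# panelfilter

Simulation-based tuning of hard filters for variant calling on targeted
amplicon gene panels.

## The problem

Small targeted gene panels — the everyday substrate of diagnostic
sequencing labs — do not have enough variants for adaptive filter
recalibration (GATK's VQSR needs whole genomes or dozens of exomes).
Calls from a panel must instead be *hard filtered*: each call is kept or
discarded by fixed thresholds on per-call quality annotations, and those
thresholds have to be chosen by the operator.  Chosen badly, they either
let through recurrent artifacts (above all false indels anchored in
homopolymer runs) or throw away true variants.

`panelfilter` turns threshold choice into a measurement.  It simulates
the panel design end to end — a catalog of SNVs/indels with population
allele frequencies, a cohort of diploid samples genotyped under
Hardy–Weinberg sampling, amplicon reads with a homopolymer-aware error
model at the study's coverage levels — calls variants, labels every call
true (TV) or false (FV) against the recorded truth, and learns
per-stratum threshold rules from classification trees.

## The statistics and the procedure

Each call carries ten filter annotations: the rank-sum z-scores
BaseQRankSum, ReadPosRankSum, ClippingRankSum, MQRankSum, plus DP, MQ,
GQ, and three statistics aimed at allele balance and strand bias.  With
AD1 and AD2 the unfiltered read counts supporting the reference and
alternate allele,

    ADT  = |AD1 − AD2| / (AD1 + AD2)
    ADTL = log10(AD1 + AD2) · ADT

so ADT ≈ 0 for a well-balanced heterozygote and 1 when only one allele
is seen, while ADTL couples the imbalance to the amount of evidence.
FS (stored as the raw p-value `FS_P`) is the two-sided Fisher exact
p-value of the 2×2 ref/alt × forward/reverse strand table.

Calls are analysed in eight strata — variant type (SNV/indel) × called
zygosity (hom/het) × coverage arm (20x "LC" / 100x "HC").  Per stratum a
CART (Gini impurity) separates TV from FV; rules are then distilled by
a node targeting/selection procedure:

1. keep descendant nodes holding ≥ 10% of the true calls with a TV/FV
   ratio > 3;
2. for each such node *l*, prefer its parent *u* when *l* keeps < 80% of
   *u*'s true calls or > 70% of *u*'s false calls;
3. each surviving node becomes one conjunctive rule (the thresholds on
   its root path); several nodes form a disjunction, and an empty
   selection means "no reliable filter — retain everything".

## Worked example

```python
import panelfilter as pf

cfg = pf.RunConfig(seed=7, n_samples=8, n_replicates=3, n_amplicons=4)
res = pf.run_pipeline(cfg)          # simulate → call → label → train → filter
print(res.results.summary())
```

```
Hard-filter rule sets (one classification tree per stratum)
==============================================================================
stratum             n_TV    n_FV  rule
------------------------------------------------------------------------------
LC_SNV_hom           103       0  N/A
LC_SNV_het           376       3  (GQ >= 12)
                                  -> retains 376/376 TV, 0/3 FV (99.2% selected)
LC_INDEL_hom          34       0  N/A
LC_INDEL_het         124     121  (GQ >= 57.5)
                                  -> retains 120/124 TV, 3/121 FV (50.2% selected)
HC_SNV_hom           103       0  N/A
HC_SNV_het           376       0  N/A
HC_INDEL_hom          34       0  N/A
HC_INDEL_het         124      60  (ADT < 0.343681)
                                  -> retains 124/124 TV, 0/60 FV (67.4% selected)
==============================================================================
```

Reading the table: at low coverage the heterozygous-SNV stratum
contained 376 true and 3 false calls; a single genotype-quality
threshold (GQ ≥ 12) removes all 3 false positives and keeps every true
variant.  Heterozygous indels are dominated by homopolymer artifacts —
at high coverage those artifacts reach GQ 99 and only allele balance
separates them, so the learned rule is an ADT threshold, while `N/A`
strata contained no false calls (or no reliable split) and are left
unfiltered.  `res.results.auc_by_stratum()` gives per-filter ROC AUCs,
`res.results.selection_table()` the pre/post-filter confusion counts,
and `res.flank_table` the recurrent 11-nt flanking windows of false
calls with their maximal homopolymer run lengths.

A command-line surface wraps the same pipeline
(`panelfilter run-all --config config.yaml --out rundir`, plus
`simulate`, `call`, `annotate`, `label`, `train`, `filter`, `evaluate`
and `flanks` subcommands over standard FASTA/FASTQ/VCF/TSV/JSON files).

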