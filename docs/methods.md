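# Methods

## Study design emulated by the simulator

The generator reproduces the structure of a targeted-panel simulation
study: a fixed panel of amplicons, a fixed variant catalog with
population allele frequencies, and replicate cohorts of diploid samples
sequenced at two coverages.  Defaults are 26 samples, 10 amplicons of
300 bp on separate pseudo-contigs, a catalog of 48 SNVs and 12 indels
(80/20), allele frequencies drawn uniformly from the grid
{1/52, …, 26/52} (the possible allele counts in a cohort of 26 diploid
individuals), 10 replicates, and coverage arms of 20x ("LC") and 100x
("HC").  Genotypes are assigned per replicate by drawing two alleles
independently with P(alt) = af, so genotype frequencies follow
Hardy–Weinberg proportions; heterozygous variants land on one randomly
chosen haplotype, homozygous ones on both.  Indels are represented
VCF-style (left-anchored, shared leading base) and normalized by the
standard right-trim/left-extend algorithm, so all representations of
one event share a single key.

Coordinates are 1-based inclusive everywhere (VCF convention).
Overlapping indels on one haplotype are resolved leftmost-first with a
logged warning.

## Read model

Reads are assigned to haplotype and strand independently with equal
probability.  By default the read length equals the amplicon length, so
every read spans its whole amplicon and the per-column depth equals the
nominal coverage — mirroring the fixed insert structure of amplicon
sequencing and producing the near-constant DP and MQ typical of such
data.  Shorter read lengths with uniform start offsets are supported;
mean per-base coverage then still equals the requested depth.

Sequencing errors are per-base and independent:

| parameter                | default | meaning                                        |
|--------------------------|---------|------------------------------------------------|
| `sub_rate`               | 0.01    | substitution probability per base              |
| `indel_rate`             | 0.001   | indel-error probability per base               |
| `homopolymer_multiplier` | 50      | factor applied to `indel_rate` inside runs     |
| `homopolymer_min_run`    | 4       | minimum run length (nt) triggering the factor  |
| `qual_mean` / `qual_sd`  | 33 / 3  | phred base-quality distribution (clipped 2–40) |

An indel error deletes the template base or duplicates it (the dominant
homopolymer length-error mode of semiconductor sequencing).  Each indel
observation is left-aligned to its canonical VCF anchor, so every
length error inside one homopolymer run pools onto a single variant
key.  This pooling is the mechanism that produces recurrent,
high-support false indel calls in low-complexity context: at 20x a run
of four or more identical bases accumulates enough concordant "errors"
to be genotyped as a variant in a sizable fraction of samples.  The
multiplier and rates were chosen once as representative of
amplicon/semiconductor error behaviour and are ordinary configuration,
not fitted values.

## Caller

Each read records its amplicon, haplotype and offset, so pileup is
exact and alignment-free; local realignment, duplicate marking and base
recalibration are out of scope (they act upstream of the statistics
studied here).  At a column, candidate alleles are the distinct
non-reference bases plus any indel token supported by at least two
reads; the most frequent candidate is genotyped under a symmetric
binomial model with per-read error ε (default 0.01, matching the
substitution rate): per read, P(obs | hom_ref) is 1−ε for ref and ε for
alt, P(obs | het) = ½, hom_alt mirrored; the call is the maximum over a
flat prior and only non-hom_ref calls are emitted.  GQ is the phred
difference between the best and second-best genotype, capped at 99.
Calls require DP ≥ 8 (below that a lone error can masquerade as a
genotype).  Rank-sum annotations are tie-corrected Mann–Whitney
z-scores oriented so that lower alt values give negative z; empty or
degenerate comparisons return 0.  The simulator emits constant mapping
quality (60) and no clipping, so MQRankSum and ClippingRankSum are ~0
by construction.

Two implementations exist — a per-read pileup path and a vectorized
batch path used by the pipeline — and a property test asserts they
produce identical calls, annotations included.

## Filter statistics

ADT = |AD1−AD2|/(AD1+AD2) and ADTL = log10(AD1+AD2)·ADT use the
unfiltered supporting read counts.  FS is the two-sided Fisher exact
p-value of the ref/alt × forward/reverse table, computed by exact
integer hypergeometric enumeration (the two-sided mass is the sum of
table probabilities not exceeding the observed one; comparisons are done
on integer numerators, so no floating tolerance enters).  It is stored
as a raw p-value and written to VCF as `FS_P`, deliberately distinct
from GATK's phred-scaled FS.  Degenerate tables (a zero margin) carry no
association and return 1.

## Trees and rule extraction

Per stratum (variant type × *called* zygosity × coverage arm) a CART is
grown on the ten annotations, pooled across replicates: Gini impurity,
candidate thresholds at midpoints between consecutive distinct values,
deterministic tie-breaks (feature order, then smaller threshold), stops
on max depth (4), node size (20), purity, or gain < 1e-4.  Missing
feature values are imputed to the stratum median for fitting and never
satisfy a rule conjunct during application (conservative).

Rule distillation: descendant nodes within the extraction depth holding
≥ 10% of the root's TVs with TV/FV > 3 are targeted; each targeted node
*l* is replaced by its parent *u* when *l* keeps < 80% of *u*'s TVs or
> 70% of *u*'s FVs.  Both percentages are interpreted relative to *u*
(the natural reading given the second criterion), and a replacement *u*
is kept whether or not it passed targeting.  Selected nodes that are
descendants of other selected nodes are dropped: their conjunctions are
strict refinements already covered by the ancestor's disjunct, so the
retained call set is provably unchanged and the rule system stays
minimal.  A selection that degenerates to the root retains everything.
Extraction depth defaults to 4 levels with a budget of 7 conjuncts per
rule; both are configuration.

## Evaluation conventions

Descriptive statistics follow the replicate-median convention: the
median per replicate first, then mean and sample sd (ddof = 1) across
replicates.  The two-group rank test is the tie-corrected two-group
Kruskal–Wallis statistic; for group sizes up to 8 its exact permutation
null is enumerated (small-sample exactness), larger groups use the χ²
(1 df) approximation.  AUC is the tie-adjusted Mann–Whitney statistic
U/(n_TV·n_FV), reported orientation-free as max(A, 1−A) so 0.5 always
means uninformative.  Undefined statistics (empty groups, single
replicate) are NaN markers, never exceptions, in report tables.

Flanking analysis takes the 11-nt reference window with the variant
locus at the 6th base; occurrences count call instances (sample ×
replicate) per locus — the only reading under which recurrent loci can
accumulate counts beyond the cohort size — and windows leaving an
amplicon are skipped with a warning.

## What passing tests do and do not show

The simulator reproduces the *structural* causes of filter behaviour:
allele-balance separation of genotypes, coverage-dependent genotype
quality, strand symmetry, and homopolymer-pooled indel errors.  It does
not model FFPE damage, tumor heterogeneity, ART-style empirical quality
profiles, alignment or clipping artifacts, or GC/primer coverage bias —
so a rule set validated here demonstrates that the tuning *procedure*
recovers the separating thresholds that exist in the data, not that any
specific threshold transfers to a given real panel.  On real data the
intended use is identical but with the user's own VCFs and truth table
as input.

## Problem sizes and determinism

The default study (10 replicates × 26 samples × 10 amplicons × 2 arms,
~600k simulated reads) runs in about a minute on one core; unit tests
use smaller cohorts.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (per stage, replicate, sample and
arm), so every artifact is a pure function of (config, seed) and reruns
are byte-identical.
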