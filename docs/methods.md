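# Methods

This note documents the models and procedures implemented in `somascape`, the
assumptions behind them, the defaults that matter, and what the synthetic
cohorts do and do not emulate.

## Coordinate conventions

Point mutations are 1-based inclusive (MAF/VCF style); intervals are 0-based
half-open (BED style). A 1-based position `p` overlaps an interval `[s, e)`
iff `s < p <= e`. Conversion happens only in `io_formats`; every analysis
module works in these conventions. Indels and multi-nucleotide variants are
excluded at read time with a logged count — all spectrum, enrichment and
landscape statistics are defined over single-base substitutions only.

## 96-context mutation spectra (`spectrum`)

Every substitution is classified by its reference trinucleotide and change,
collapsed to the pyrimidine strand: a purine-centered mutation and its flanks
are reverse-complemented, so the 96 classes are the six changes C>A, C>G, C>T,
T>A, T>C, T>G times 16 flank combinations, ordered alphabetically from
`A[C>A]A` to `T[T>G]T`. Raw class counts are normalized by the frequency of
the class's reference trinucleotide among all overlapping 3-mer windows of the
(optionally masked) genome, counted with the same pyrimidine collapse; windows
containing an ambiguous base are skipped, and an empty frequency bin is an
error because the normalization is undefined there. Mutations at contig edges
(no flanking base) are excluded with a logged count.

Cohort PCA treats samples as observations and the 96 bins as variables.
Variables are centered but deliberately not unit-scaled, so that high-rate
contexts (in methylated genomes, C>T at CpG) are allowed to dominate the
leading component — that domination is the signal of interest, not a nuisance.
The PCA input is the genome-normalized rates by default, with per-sample
proportions as an option (`use="proportions"`); component signs are fixed so
each component's largest-magnitude loading is positive, making scores
reproducible across sample orderings.

## Signature refitting (`signatures`)

Each sample's 96-bin count vector `m` is decomposed against a column-stochastic
catalogue `S` (96 x K) by

    minimize over w >= 0 :   || S w - m ||_2^2 + lambda * || w ||_1 ,

with no intercept. Fitting uses raw counts rather than genome-normalized
rates because catalogue columns are probability distributions over observed
mutation classes; the normalized rates exist for visualization and PCA. The
choice is a function argument, not hard-coded.

Solver: cyclic coordinate descent with nonnegative soft-thresholding
(`w_j <- max(0, (S_j . r_j - lambda/2) / ||S_j||^2)`), converged when the
largest coordinate change in a sweep falls below 1e-9 (cap 10,000 sweeps).
This is exact for the separable penalty; the test suite verifies the attained
objective against an independent bound-constrained quasi-Newton solver on 200
random instances (the L1 term is linear on the nonnegative orthant, so the
problem is a smooth box-constrained QP for the oracle).

Penalty selection is per sample: the 96 bins are shuffled into 10
cross-validation folds, the model is fitted along a 50-point log-spaced grid
from `lambda_max` (the smallest penalty that zeroes the fit, `2 max_j S_j.m`)
down to `1e-4 * lambda_max` with warm starts, and held-out mean-square error
is averaged across folds. The selected penalty is the largest grid value
whose CV error stays within one standard error (taken at the minimizing
penalty) of the minimum — maximal sparsity within one SE. The final weights
are refit on all 96 bins. CV folds are over context bins because a per-sample
regression with a fixed design has no other axis to resample; fold assignment
is seeded and the selected support is stable across fold seeds on
well-separated instances. Signatures contributing less than 5% of the fitted
total are then discarded and the remainder renormalized; pooled cohort
summaries sum count-scale weights over samples before normalizing.

## APOBEC TCW enrichment (`apobec`)

Qualifying mutations are C>{T,G} and G>{A,C}; a qualifying mutation is a motif
hit when its reference trinucleotide is T-C-W on the pyrimidine strand or
W-G-A on the purine strand (W = A or T). For each qualifying mutation the
reference sequence +/-20 bp (clipped at contig edges) contributes to the
context pool; overlapping windows are counted with multiplicity, and the
mutated base itself is included. The enrichment fold is

    fold = (mut_TCW * ctx_C) / (mut_C * ctx_TCW)

with `ctx_TCW` the TCW+WGA occurrences and `ctx_C` the C+G bases in the pooled
windows. Significance is a one-sided Fisher exact test on
`[[mut_TCW, mut_C - mut_TCW], [ctx_TCW, ctx_C - ctx_TCW]]` (over-representation
among mutations), Benjamini-Hochberg corrected across the samples of one
invocation. A sample is called enriched when the adjusted p-value is below
alpha (default 0.05) **and** the fold exceeds one; degenerate counts (no
qualifying mutations, or a motif-free context) are flagged untestable rather
than tested.

## Mutation landscape (`landscape`)

DHS burden is a point-in-interval count per sample. Replication timing per
mutation is computed per cell-type track as the length-weighted mean of the
step signal over a +/-10 kb window — uncovered bases are ignored, and a track
covering less than half the window is unusable for that mutation — then the
median across cell types is taken; mutations inside the supplied exclusion
regions (exome with flank, gaps, blacklist) are dropped. "Early-replicating"
mutations are those strictly above the 90th percentile (linear-interpolation
quantile) of all pooled, non-excluded mutation times; ties at the threshold
fall below, and the statistic is invariant to monotone transforms of the
signal. Group comparisons are one-sided Wilcoxon rank-sum tests, exact for
combined n <= 20 without ties and normal-approximated with tie correction
otherwise. Regional recurrence counts a sample once per region regardless of
its number of hits. Chromatin-remodeler status flags a sample carrying a
truncating mutation (nonsense, frameshift, splice) in a listed gene, or a
missense with impact score >= 0.9; a missense lacking a score counts with a
warning unless strict mode is on.

## Structural variants (`sv_filter`)

Quality filtering drops calls flagged LowQual and, in addition, re-derives the
rule from the evidence fields: paired-end AND split-read support both below 3
(either evidence type suffices to keep a call), or mapping quality below 20.
Re-derivation guards against inconsistently pre-flagged tables and can be
disabled (`flag_only`). Population (germline) filtering drops a call when a
population record of the **same type** reciprocally overlaps it by >= 0.8
(`min(ov/|a|, ov/|b|)`); type stratification is a deliberate choice — a
deletion is not evidence against a duplication at the same locus.
Translocations are matched by breakpoint proximity instead (both ends within
1 kb by default). Samples are classed genome-stable below 10 post-filter
events and genome-unstable above 40; the `[10, 40]` gap is reported as
"intermediate" because the thresholds as stated leave it undefined. The
tree-input prefilter drops SNVs inside copy-number segments with
|log2 ratio| > 0.3 (strictly) and SNVs with allele fraction > 0.6.

## Cohort statistics (`cohort`)

Minor allele frequency is `(HET + 2*ALT_HOM) / (2 * n_genotyped)` with missing
genotypes excluded from the denominator. A death is cancer-specific when the
tumor status reads "With Tumor"; when tumor status is unrecorded, when the
patient had M1 disease, nodal involvement >= N1, or died within two years
(<= 730 days). Follow-up time is days-to-death for the deceased and
days-of-follow-up for the censored. Group curves are Kaplan-Meier estimates;
differences are tested with the standard log-rank statistic and the Peto &
Peto modification of the Gehan-Wilcoxon test (weights from the pooled modified
survival estimate), both via lifelines with chi-square p-values. The 2x2
association test reports the odds ratio (Haldane 0.5 correction only when a
zero cell would make it undefined, and flagged) with the exact two-tailed
Fisher p on the uncorrected counts. Differential methylation drops sites with
missing values or on excluded chromosomes, tests each remaining site with a
two-sided rank-sum between clusters, adjusts by Benjamini-Hochberg, and calls
a site hypermethylated only when adjusted p < 0.05 **and** the cluster-mean
beta difference is >= 0.2 — the effect-size floor is what keeps marginally
significant, biologically negligible shifts out of the call set.

## Synthetic cohorts (`synthetic`)

The generator's defaults are the package's standard study conditions, chosen
once to mirror the emulated cohort design:

| parameter | default | rationale |
|---|---|---|
| genome | 200 kb, one contig, base composition (0.3, 0.2, 0.2, 0.3) | smallest size at which all 32 trinucleotide bins are well populated |
| cohort | 35 samples, 900 mutations each | WGS-scale per-sample burden at desk scale |
| DHS track | 12% of genome in 1-kb blocks | open-chromatin fraction of a typical tissue |
| DHS depletion | rate ratio 0.6 in wild-type samples; 9/35 remodeler-mutant samples place uniformly | yields a ~1.6x wild-type→mutant shift in median DHS mutation counts |
| APOBEC | TCW-bin boost (default off); context-matched null catalogue | the null catalogue draws bins in proportion to genomic context availability so the enrichment fold is ~1 by construction |
| survival | n=96, 7 heterozygous carriers, hazard ratio 3, exponential baseline median 1200 d, administrative censoring at 2000 d | the risk-allele survival design at its published carrier count |
| methylation | 100 sites x 96 samples, 10 true sites shifted +0.3 beta, Beta-distributed at concentration 50 | two-cluster array structure with an unambiguous truth set |
| SVs | 29 stable (< 10 events) + 6 unstable (41–88) samples; 2 low-quality and 1 germline-overlap decoy per sample, plus one type-mismatched population probe | exercises every branch of the filters; decoys live in a reserved coordinate band so the designed truth labels cannot be blurred by accidental overlaps |

Mutations are drawn per sample from the exposure-weighted mixture of catalogue
signatures and placed uniformly among genome positions whose
pyrimidine-collapsed context matches the drawn bin, so simulated and analyzed
bins coincide by construction. Determinism: one global seed fans out to
substreams keyed by operation and sample index, so adding a sample never
perturbs existing samples' draws; every simulation emits a ground-truth
manifest.

What the generator does **not** emulate: mutation clustering (kataegis),
sequencing/calling noise, mappability gaps and blacklist regions, copy-number
structure, subclonal architecture, correlated signature exposures across
samples, or array batch effects. Passing recovery tests therefore demonstrate
correctness of the computations under the stated generative model, not
robustness to real-data artifacts.

## Problem sizes and numerics

The acceptance studies run at: 20 samples x 10,000 mutations against a
30-signature catalogue (exposure recovery); 200 random K <= 6 instances
(solver/oracle agreement, tolerance 1e-6 on the objective); 100 null and 31
detection samples x 500 mutations (APOBEC calibration); 100 replicates of the
35-sample DHS comparison; 200 replicates each of the hazard-ratio-3 and
null survival designs. Exact tests (Fisher, small-sample rank-sum, toy
log-rank) are checked against exhaustive enumeration; interval machinery is
checked exhaustively against per-base oracles on 50-bp toys. Coordinate
descent uses tolerance 1e-9 on the largest coordinate change; catalogue
columns must be stochastic within 1e-6; ties in the one-SE rule break toward
the larger penalty (maximum sparsity).

## Known limitations

- The CV-fold axis for per-sample penalty selection (context bins) is a
  modelling choice; bootstrapping mutations would be an alternative with
  different variance properties.
- The Peto-Peto weights follow lifelines' modified survival estimate
  `prod(1 - d/(n+1))`; other texts use the left-continuous pooled KM estimate,
  which differs at event times by O(1/n).
- `enrichment_scan` corrects across the samples of one invocation; combining
  runs requires re-correction by the caller.
- The VCF reader handles minimal single-sample files only; multi-sample VCFs
  must be split upstream.
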