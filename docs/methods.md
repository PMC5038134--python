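# Methods

`rarecnv` implements a case–control analysis of rare copy-number
variants (CNVs): deletions and duplications >1 kb called from SNP-array
intensity data, restricted to events present in <1% of individuals.
Three complementary analyses are provided, each exposed as a model
object whose `fit()` returns a results object with estimates,
uncertainties and a `summary()` table.

1. **Locus association** — carrier counts at predefined recurrent-CNV
   regions (the bundled catalogue holds 15 loci previously implicated
   in schizophrenia, in hg19 coordinates) compared between cases and
   controls with a two-sided Fisher's exact test.
2. **Gene scan** — a genome-wide test, per gene and per CNV type, of
   the number of samples carrying an exon-disrupting CNV >10 kb.
3. **Burden analysis** — size-stratified comparison of per-individual
   CNV event counts between two groups with a label-permutation test.

## Quality control

Sample-level QC excludes individuals whose array metrics (Log R Ratio
s.d., B-allele-frequency drift, wave factor, total CNV count) are
outliers *within their own source cohort*, since intensity statistics
are array- and batch-specific. The outlier rule is
`metric outside [median − k·IQR, median + k·IQR]` with `k = 3` by
default; a zero-IQR (constant) metric flags any deviation from the
median. Cohorts of fewer than 8 samples are refused — quartiles of a
handful of points are not robust.

Call-level QC has three independent filters:

* **Frequency.** A call's population frequency is the number of
  distinct samples (cases and controls pooled — the PLINK convention;
  the denominator choice matters only in heavily unbalanced designs)
  carrying a same-type call with ≥50% reciprocal overlap, divided by
  the roster size. Calls at frequency ≥1% are removed. Frequencies are
  computed on the *input* call set, so the filter is order-independent
  and idempotent.
* **Size.** Strata use a strict lower and inclusive upper bound,
  `min < length ≤ max`, so the burden strata (500 kb, 1 Mb] and
  (1 Mb, ∞) partition the >500 kb calls exactly.
* **Probe support.** Calls annotated with fewer than 10 supporting
  probes are dropped (calls without probe annotation are kept).

Intensity validation uses a **median Z-score**: over the probes inside
the call interval, each sample's median Log R Ratio is computed; the
carrier's median is standardised against the mean and s.d. (ddof = 1)
of *all* samples' medians. A deletion validates at `z ≤ −2`, a
duplication at `z ≥ +2` (threshold configurable). The reference
distribution is pooled across cohorts; a cohort-specific variant would
only matter under strong batch structure, which the upstream
probe-intersection step is assumed to have mitigated. The statistic is
invariant under adding a constant to the whole matrix, and a degenerate
zero-s.d. matrix yields `z = 0` (never validated). Only LRR is used;
BAF-based validation is out of scope.

Sex-chromosome calls are excluded by default (`autosomes_only`):
intensity-based CNV calling on X/Y is confounded by sex, and none of
the target loci are gonosomal.

## Locus association

A call matches a locus iff its type equals the locus type and the
overlap covers ≥50% of the *locus* length (`min_locus_coverage`); a
duplication can therefore never count at a deletion locus. Carriers are
distinct samples — several matching calls in one individual count once.
Counts from multiple case sources are pooled by summing carriers and
totals *before* testing (counts, not p-values, are combined); cohorts
must be non-overlapping, which is the caller's responsibility.

For the 2×2 table (a = case carriers, b = case non-carriers, c, d
likewise for controls):

* **p-value**: two-sided Fisher's exact test under the "minlike"
  convention — the sum of hypergeometric probabilities of all tables
  with the same margins whose point probability is ≤ the observed one
  (with a 1 + 1e−7 relative tolerance for floating-point ties). A zero
  margin gives p = 1. The implementation delegates to
  `scipy.stats.fisher_exact`, which uses exactly this convention; the
  test suite checks it against full hypergeometric enumeration for all
  margins ≤ 30.
* **Odds ratio**: OR = ad/bc, reported as undefined (`NA`) whenever any
  cell is zero. No Haldane–Anscombe correction is applied — an
  undefined OR is more honest than a pseudo-count estimate at these
  carrier counts.
* **Confidence interval**: Woolf's log-OR normal interval,
  `exp(ln OR ± z₁₋α/₂ √(1/a + 1/b + 1/c + 1/d))`, without continuity
  correction. This choice reproduces published interval bounds from
  their counts exactly, and its empirical coverage is checked by
  simulation.
* **Genome-wide significance**: Bonferroni over the ~120 genomic
  regions prone to recurrent CNVs, threshold 0.05/120 ≈ 4.17 × 10⁻⁴.
  The unrounded value is used throughout (rounded citations of this
  threshold vary between 4.1 and 4.2 × 10⁻⁴; the comparison is made
  against the exact quotient).

A two-proportion **power calculator** is included: the case frequency
implied by a control frequency f and odds ratio is
`f·OR/(1 − f + f·OR)` (odds transform), and power is the standard
two-sided normal approximation with unpooled variances. At OR = 1 it
returns exactly α. It is validated against the Monte-Carlo rejection
rate of the Fisher test in a regime where the normal approximation is
adequate (moderate frequencies); for very rare carriers the exact test
is conservative relative to the approximation.

## Gene scan

A call is an **exonic hit** on a gene iff it overlaps ≥1 bp of ≥1 exon.
Gene models are merged per gene symbol (exon union over transcripts)
and include non-coding RNAs; any exon counts, not only coding exons.
Calls ≤10 kb are excluded (strict inequality), as are calls matching
any excluded locus under the locus-association rule — by default the
bundled 15-locus catalogue, so known recurrent loci do not re-surface
as "novel" genes. Deletions and duplications are tested separately with
the same Fisher machinery; the gene-wide threshold is
0.05/20 000 = 2.5 × 10⁻⁶ per CNV type. A call disrupting exons of two
overlapping genes counts toward both.

Nominally significant genes (p < 0.05) are **collapsed into regions**:
same-type genes on one chromosome whose transcript intervals lie within
1 Mb of each other (transitively) share a region id. This is a
proximity heuristic — a single multi-gene CNV should be read as one
signal, not many — implemented as a sorted sweep and verified against
graph connected components. It is a grouping aid, not a claim about
haplotype structure.

Manual review of candidate regions (intensity traces, B-allele
frequencies) is inherently out of automated scope; the median Z-score
validator can be applied per carrier call as a screening diagnostic.

## Burden analysis

The burden metric is the **CNV event count per individual** — a sample
with three qualifying duplications contributes 3 — not the carrier
proportion; group rates are reported as events per 100 samples.
Strata are (500 kb, 1 Mb] and (1 Mb, ∞), deletions and duplications
separate. Only these largest classes are compared because burden
estimates for smaller CNVs are dominated by array-specific sensitivity.

Significance uses a label-permutation test with statistic
`T = |mean(counts_A) − mean(counts_B)|`, two-sided by construction
(symmetric in the groups by design; whether the original analyses
doubled a one-sided tail instead is not documented, so the symmetric
statistic is this package's explicit choice). Group labels are permuted
uniformly, and

    p = (1 + #{T_perm ≥ T_obs}) / (1 + n_perm)

with 10 000 permutations by default. The +1/+1 correction keeps the
estimator unbiased under the null and never returns 0; ties count as
exceedances (conservative), with a 1e−12 absolute slack on the
comparison to absorb floating-point noise in the means. The seed is
recorded in every result; a fixed seed reproduces the p-value exactly.
When only aggregate event counts are published, `BurdenModel.from_counts`
reconstructs count vectors by assigning one event per distinct sample —
a documented approximation, exact whenever no individual carries two
events in the same stratum. The repeat analysis with known recurrent
loci removed is supported via `remove_locus_cnvs` / `exclude_loci`.

## Synthetic data

The generator emulates the statistical structure the pipeline is built
for, with defaults at the study scale: 2 591 cases vs 8 842 controls;
background rare CNVs per sample ~ Poisson(3) with log-uniform sizes on
10 kb–2 Mb and uniform positions (a few rare CNVs >10 kb per genome is
the typical post-QC yield on dense arrays); planted locus carriage with
control frequency f and case frequency `f·OR/(1−f+f·OR)` (the odds
transform, because the targeted effect sizes are odds ratios); optional
planted common (≥1%) CNV groups and planted QC-outlier samples; a toy
genome of 2 chromosomes × 50 Mb carrying 200 deterministic 10-exon
genes — large enough for interval edge cases, small enough for
per-basepair oracle tests. LRR matrices use carrier shifts of −0.45
(deletion) and +0.30 (duplication) over N(0, 0.15) noise — typical
array magnitudes, configurable, and not estimates of any particular
platform.

What it does **not** emulate: batch/array effects and probe-set
differences between cohorts, GC waves, BAF, correlated probe noise,
segmental-duplication-mediated hotspot architecture, or calling
artefacts. Passing tests on synthetic cohorts therefore demonstrate the
correctness and calibration of the statistics given clean calls, not
robustness to the technical biases that dominate real CNV studies —
those must be addressed upstream (probe intersection, per-batch
calling, manual review).

## Numerical and testing choices

* Internal coordinates are 1-based inclusive (PLINK convention); BED
  and refFlat convert at the I/O boundary. Chromosomes are `1`–`22`,
  `X`, `Y`, ordered in that sequence in outputs.
* The bundled locus catalogue uses the published Mb positions truncated
  to 10 kb resolution verbatim, rather than any external curated
  interval set.
* Rendered tables round to 2 significant figures; machine TSVs carry
  full precision. Renderers are pure functions of the machine results.
* Test problem sizes are chosen so independent oracles stay exact and
  fast: exhaustive Fisher enumeration at margins ≤ 30, all-pairs
  overlap grouping at ≤ 500 calls, per-basepair exon intersection on a
  1 Mb window, exhaustive permutation at n = 12, 100-seed
  coverage runs and 400-replicate calibration runs.
* The Woolf-coverage recovery test plants a carrier-informative control
  frequency (3 × 10⁻³) at the study's sample-size scale; at the rarest
  published locus frequencies (~3 × 10⁻⁴) expected carrier counts of
  ~3 per arm make zero cells — and hence undefined CIs — common, so
  coverage of a defined interval is the meaningful property to test.

## Limitations

* No genome-build liftover; all coordinates are assumed hg19.
* No covariate-adjusted burden model (no batch regression) and no
  stratified (Mantel–Haenszel) locus estimator — counts are pooled
  raw, which is only valid when per-cohort ascertainment is comparable.
* The CNV calls themselves are inputs: no intensity segmentation or
  calling algorithm is included.
* The permutation test conditions on the observed count vectors;
  with very sparse data its p-values are conservative (discrete
  support), which the calibration tests quantify.
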