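# Methods

This note records the models, conventions and numerical choices behind
`regenrich`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and interval arithmetic

All intervals are 0-based half-open (BED convention) internally; 1-based
inputs — SNP tables and GTF — are converted at the reader boundary, and a
leading `chr` prefix is stripped on read (configurable), since bovine
references mix naming dialects. Peaks are strand-less; strand matters only
for gene TSS and upstream regions. Coverage, consensus and intersection are
computed with sorted-endpoint sweeps over integer arrays and are tested for
exact agreement with per-base bitmap oracles on small genomes.

Consensus peaks are the maximal runs of bases covered in at least
`min_support` samples (default 2). Support is counted per sample: two
overlapping intervals from the same replicate contribute one vote, because
the unit of replication is the sample, not the interval. Each output
interval carries the maximum per-base support as its score. With
`min_support=1` the consensus equals the merged union; raising the
threshold can only shrink coverage. Consensus is built per mark across all
tissues and animals jointly; callers can pass any subset of peak sets to
change that.

## Gene activity and upstream regions

A gene is *active* in a tissue when every sample of that tissue has a count
strictly above 200, *inactive* when every sample is strictly below 10, and
*ambiguous* otherwise; "over 200" and "less than 10" are read strictly.
Tissue-specific active genes are active in the focal tissue with all
samples of every other tissue below 10. Counts are used as provided
(normalized upstream); the thresholds are on that scale.

The TSS is the gene's 5′ end on its strand (5′-most transcript start when a
GTF provides transcripts). The promoter is the 2 kb immediately upstream of
the TSS; the proximal region is the 8 kb immediately upstream of the
promoter's upstream edge. Both are strand-aware, clipped at chromosome
bounds, and by construction never overlap each other for the same gene.

## Counting and TMM normalization

Fragments are counted into consensus peaks by any ≥ 1 bp overlap; a
fragment spanning k peaks increments all k. Library sizes are the total
fragments per sample when supplied ("full library size"); otherwise column
sums are used with a warning.

TMM factors follow the trimmed-mean-of-M-values scheme: reference = sample
whose upper-quartile of library-scaled counts is closest to the mean
upper-quartile; per sample, features positive in both it and the reference
contribute M (log2 ratio of scaled proportions) and A (mean log2
abundance); the top and bottom 30% of M and 5% of A (tie-averaged ranks)
are discarded and the rest averaged with inverse delta-method variance
weights; factors are re-centered to geometric mean 1. A unit test checks
agreement with Bioconductor edgeR's `calcNormFactors` to 1e-8 on a
composition-biased matrix. Note that the M-values are scale-free but the
precision weights are not, so factors are invariant to rescaling one sample
only to within a percent or two — a property of the canonical algorithm,
not of this implementation. CPM uses a prior count of 0.5 (configurable) so
log transforms stay finite at zero.

## Differential binding

Signal is TMM-normalized log2-CPM. The fold for a peak is the difference
between the focal-tissue mean and the mean of all other tissues (mean over
samples by default; mean of tissue means optionally, which matters only for
unbalanced designs). The p-value comes from a Welch two-sample t-test of
focal versus rest samples, and a peak is called differentially bound when
p < 0.05 and |log2 fold| > 1. The t-test stands in for a negative-binomial
GLM deliberately: with 2–3 replicates per tissue the call set is dominated
by the 2-fold filter, and the p-value function is pluggable for anyone who
wants a different test. At n = 3 focal samples the Welch p on log-NB counts
is mildly liberal (null rate ≈ 0.06–0.08 at α = 0.05); the joint criterion
stays far below 1% on nulls, which is the property the pipeline relies on.
No multiple-testing correction is applied (raw p is the published
convention for this screen); a BH column is trivial to add downstream.

## Peak–expression correlation screen

Peaks pair with every gene whose TSS lies within 100 kb of the peak anchor
(summit for narrow marks, midpoint for broad ones). Pearson r is computed
across the matched sample panel, with the two-sided p from the t-transform
on n − 2 degrees of freedom; pairs with a zero-variance vector are flagged
NaN and excluded from summaries. The screen is uncorrected by design: its
readout is the excess of the significant fraction over the 5% chance level
and the sign balance (repressive marks correlate negatively). One matched
panel per mark is assumed; mixing panels of different sizes within a mark
is the caller's responsibility.

## Variant enrichment

`fold = (C/A)/(B/D)` is evaluated in the exact algebraic form `C·D/(A·B)`.
Only autosomes enter (the genome size D is the sum of autosome lengths).
SNP positions are deduplicated on construction, and a SNP at 1-based
position p is "under" a half-open region iff start ≤ p−1 < end. Tails are
one-sided hypergeometric with the observed C included in both
(`P(X ≥ C)` and `P(X ≤ C)`), treating base positions as exchangeable; both
are reported because either enrichment or depletion can be of interest.
Discreteness makes the test conservative at small expected counts.

Distance stratification assigns regions to 100-kb bands by anchor distance
to the nearest TSS and SNPs by their own distance; D is the number of
genomic bases whose distance falls in the band (a flag switches to global
D). Bands with fewer than 10 SNPs are reported NA rather than as unstable
estimates. Positions on chromosomes without any TSS are excluded with a
log message. Chromatin-state overlap enrichment applies the same fold with
bp in both roles (A = state bp, B = annotation bp, C = intersection bp).

## LD pruning

r² is the squared Pearson correlation of 0/1/2 dosages over
pairwise-complete individuals (a zero-variance SNP never prunes or is
pruned, with a warning). Windows start every 50 SNPs and span 1 Mb; within
a window SNPs are scanned in genomic order (or ascending p-value in
`by_pvalue` mode) and dropped on r² ≥ 0.5 against any already-retained SNP;
the sweep repeats until stable. The exact removal order of other tools is
not reproduced — the normative contract, asserted exhaustively in tests, is
that no retained pair within any window reaches the threshold, that pruning
is idempotent, and that `by_pvalue` keeps each LD block's most significant
SNP.

## Synthetic data: what it emulates and what it does not

The generators mirror the study design the pipeline targets: 6 tissues ×
3 animals; narrow marks ≈ 500 bp and broad marks ≈ 1100 bp mean width;
replicate peak sets derived from a latent skeleton with 15% dropout and
±50 bp edge jitter; negative-binomial counts (gamma–Poisson, dispersion
0.1) with lognormal library sizes; a planted 4-fold tissue effect on a
subset of peaks; planted peak–gene couplings via a shared gamma component
whose mixing weight is solved analytically so the count-scale Pearson r
hits the target (0.9 by default); activity-rule genes drawn to satisfy the
all-samples thresholds exactly; SNP sets whose fold enrichment inside
regions is planted exactly (each SNP falls inside with probability ρ·A/D,
making the fold estimator unbiased for ρ at any region coverage, also
band-restricted); block-LD genotypes with within-block r² set via the flip
probability ε in r² = (1−2ε)⁴; and a 7-state chromatin tiling whose
"active promoter" state is biased onto planted-active promoters.

The default genome is 10 chromosomes × 5 Mb — large enough that every
100-kb distance band out to 1 Mb is populated (genes occupy only the first
half of each chromosome precisely so that large TSS distances exist), and
small enough that a full pipeline run takes seconds. Everything is a pure
function of (config, seed); per-mark streams are salted with a CRC of the
mark name so they are stable across processes.

Real data differ in ways the simulations do not capture: mappability and
GC structure, correlated replicates and batch effects, peak-width and
signal heterogeneity within a mark, LD that decays continuously rather
than in clean blocks, and SNP ascertainment. Passing tests therefore
demonstrate the correctness and calibration of the *statistics* under
their stated models, not robustness to those artefacts.

## Test and acceptance problem sizes

The self-checks use sizes chosen to make Monte-Carlo error small relative
to each tolerance: 500 replicates of 500 uniform SNPs for null
calibration; three panels of 10⁴ SNPs per planted fold; 3 × 10⁵ SNPs for
the distance-band profile (so each far band holds ~10³ SNPs and the
per-band fold SE is ≈ 0.05); 2000 peaks with 200 planted for differential
binding; 30,000 null pairs for the correlation screen. Fixed seeds make
every run reproducible; the reported quantities are recomputed from
scratch each time by `scripts/acceptance.py`.
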