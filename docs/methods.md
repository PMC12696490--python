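# Methods

## Model

A male diploid cell carries one chrY and two copies of each autosome. If a
fraction CF of a sample's cells have lost chrY, the expected chrY read
depth is proportional to (1 − CF)/2 of the autosomal level. All estimation
in this package is an inversion of that dosage relation:

    covY = 0.5 · (1 − CF)   ⇔   CF = 1 − 2·covY   (clamped to [0, 1])

and, for genotyping-array intensities, mLRRY = log2(1 − CF)/2, inverted as
CF(%) = 100 × (1 − 2^(2·mLRRY)), clamped to [0, 100]. The coverage
conversion returns fractions; the mLRRY conversion is reported in percent
by convention (`as_percent` switches). Clamping outside the physical domain
is silent because the piecewise forms define it; a positive mLRRY (a gain
signal) maps to CF = 0.

The per-sample coverage statistic is deliberately median-based at every
level — median per-base depth within an exon, median depth over an exon's
matched set, median of per-exon ratios, median-centred cohort rescale,
quartile-based threshold — so single aberrant exons, CNVs in a matched
exon, or a minority of outlier samples perturb the estimate only through
order statistics.

## Region panels

The chrY panel is restricted to exons of the 13 single-copy X-degenerate
MSY genes. Ampliconic gene families vary in copy number between normal
individuals and X-transposed regions cross-map with chrX, so both would
corrupt a dosage estimate; single-copy genes make depth proportional to
chrY copy number.

Each chrY exon is matched to k = 100 autosomal exons (without replacement)
by nearest-neighbour propensity score: a logistic regression of chrY
membership on standardized GC fraction and log10(length), matched on the
linear predictor. GC and length are the two dominant determinants of
capture efficiency, so normalizing each chrY exon to its matched set
cancels sample-specific GC bias without fitting per-sample correction
curves (the GC-bias cancellation test demonstrates exactly this: a strong
simulated GC trend moves the estimate only when matching is deliberately
GC-blind). Greedy assignment runs over chrY exons in decreasing length
(the hardest exons to match get first pick), with distance ties broken by
genomic order, making the match list deterministic; matching without
replacement keeps matched sets disjoint so no autosomal exon dominates
several ratios. Candidates on sex chromosomes or non-primary contigs are
excluded, as are exons with more than 50% ambiguous reference bases (they
carry no GC signal; GC itself is computed over unambiguous bases only).
Autosomal exons with ≥ 10 recorded mosaic gains/losses in blood are
excluded before matching; absence from the blacklist counts as zero events,
since such files enumerate only regions where events were seen.

An optional curation step drops chrY exons whose coverage is an outlier
across reference samples believed mLOY-free: the per-exon statistic is the
median across samples of exon depth over the sample's autosomal median, and
exons outside median ± 1.5×IQR of that statistic are removed. The rule and
multiplier are parameters; the default minimum of 20 reference samples
keeps the per-exon medians stable.

## Coverage

Per-exon median depth comes either from coordinate-sorted, indexed
BAM/CRAM (per-base accumulation over aligned blocks, so soft-clipped and
spliced-out segments contribute nothing) or from imported per-region
tables. Defaults mirror the common per-region coverage tool: unmapped,
secondary, supplementary and duplicate reads are excluded; no mapping
quality floor; overlapping mates count twice (`correct_mate_overlap`
switches to per-fragment counting). The median of an even-length set is
the mean of the two central values; this and the quantile convention below
are fixed for bit-reproducibility. CRAM requires an explicit reference
path — nothing is ever downloaded.

Downsampling robustness is modelled at depth level: each depth d is
replaced by Binomial(round(d), keep_fraction), which has the right mean and
the right variance contraction for read-level thinning of independent
reads, without invoking an external resampling tool.

## Normalization, thresholding, calling

cov_raw is the median over chrY exons of depth(e)/median(matched depths).
Exons with missing depth, or with a zero matched-set median, are dropped
from the sample's median and QC-flagged (`high_missing` above 20%
missingness); a sample with no usable exon is an error, not a silent zero.
Medians tolerate missingness, but heavy loss must surface.

The cohort rescale (cov_scaled = cov_raw − cohort median + 0.5) is a pure
translation: ranks, the IQR and therefore the Tukey fence all shift with
it, so binary calls are provably identical before and after. Calibrations
store the median on the raw scale and the threshold on both scales
(threshold_raw = threshold_scaled + median_raw − 0.5); single-sample
calling compares on the raw scale, which is algebraically identical to the
scaled comparison and is asserted equal in tests. Rescaling refuses
cohorts under 50 samples (configurable): quartiles of smaller cohorts are
too unstable to define a threshold, and single-sample mode with a stored
calibration is the supported path. Multi-batch data are rescaled per batch
and then pooled, never the reverse, since batch-level coverage shifts would
otherwise leak into the pooled threshold.

The binary rule is the standard lower outlier fence, Q1 − 1.5×IQR, with
strict `<` at the boundary so ties are deterministic. Quantiles use linear
interpolation between order statistics (numpy's default, R type 7)
everywhere. No cohort-size-adaptive threshold is attempted; for broad
(tumor) distributions where the statistical fence falls implausibly low,
the fixed cell-fraction mode (carrier iff covY ≤ 0.5 − CF_cut/2, inclusive
so the boundary sample carrying exactly CF_cut is a carrier) is the
documented alternative.

Concordance between two call sets uses the cross-product odds ratio with
no continuity correction and Fisher's exact two-sided p by the
probability-mass rule; both choices are validated against full
hypergeometric enumeration in tests.

## Synthetic cohorts

The generator emulates the study conditions the estimator is designed for:
autosomal exon depth ~ NB(mean_depth × gc_trend(gc)), chrY exon depth ~
NB(0.5 × (1 − f) × mean_depth × gc_trend(gc)), with f the sample's true
cell fraction (0 for non-carriers, so cohort-level mean CF is computable
over everyone). Defaults: 500 samples, 10% carrier prevalence, carrier
cell fractions uniform on [0.1, 0.8], 50× mean depth, negative-binomial
overdispersion 0.05 (mild extra-Poisson variation, typical of within-panel
exome depth once GC is controlled), and a concave log-depth GC trend
(coefficients (0, −3) in gc − 0.5) depressing coverage at extreme GC as
capture chemistry does. The default synthetic panel is 13 pseudo-genes ×
13 exons = 169 chrY exons, mirroring the size of a real single-copy panel,
with a 25,000-exon autosomal candidate pool wide enough for k = 100
matching without replacement; the generated study runs the real matcher,
so simulation exercises the production code path. Optional per-batch
multiplicative chrY biases emulate kit/batch effects.

What the simulator does not model: alignability artifacts, cross-mapping
from ampliconic genes, CNVs inside the matched autosomal pool, correlated
noise between neighbouring exons, and contamination. Passing tests
therefore demonstrate correctness of the estimation pipeline under
GC-biased, overdispersed dosage data — not robustness to every artifact of
real capture data, which is why the panel-curation steps (CNV blacklist,
outlier-exon filter) exist as inputs rather than being validated here.

Miniature alignment fixtures (a random reference plus sorted, indexed
BAMs whose per-exon depth hits a requested target, exactly under uniform
tiling or in expectation under Poisson read placement) allow the native
pileup path to be checked against an independent per-column counting
engine on arbitrary layouts.

## Problem sizes and determinism

Test and demonstration cohorts use the full 169-exon panel at 500 samples
for distribution-level claims, and reduced panels (12–30 exons, k = 8–20,
80–200 samples) for pipeline-level tests; these sizes give stable medians
and quartiles while keeping the suite quick to run. All stochastic steps
take explicit seeds (numpy Generator); identical configuration and seed
reproduce byte-identical output tables, and the propensity matcher is
deterministic outright.

## Known limitations

- The method estimates loss only; mosaic chrY gains would appear as
  covY > 0.5 and are clamped to CF = 0.
- Calibrations are capture-kit-specific; applying one across kits is
  refused by default and should only be overridden for kits with verified
  identical chrY capture behaviour.
- Very small clones (CF below roughly twice the cohort's coverage noise)
  are indistinguishable from noise under the fence rule; the fixed-CF mode
  makes the detection floor explicit instead.
- cov_raw is a ratio of medians of noisy depths; at very low depth (≪10×)
  its small upward bias (Jensen effect of the reciprocal) is no longer
  negligible, visible in the depth-series recovery test.
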