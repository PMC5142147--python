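# Methods

## The gap-hunting procedure

Per probe, the non-missing beta values are sorted and consecutive
differences taken; a difference **strictly greater** than `threshold`
(default 0.05, beta units) is a gap, and a probe with at least one gap is
a gap signal with `n_groups = n_gaps + 1`. Group labels run 1..k in
ascending beta order; cutpoints are the midpoints of the flanking values
of each gap. A call is *outlier-driven* when the samples outside the
single largest group number **no more than** `out_cutoff * n` (default
0.01); such calls are removed unless `keep_outlier_driven` is set.

Boundary conventions are deliberate and covered by boundary tests: a
difference exactly equal to the threshold is not a gap (strict
comparison), while the outlier rule is non-strict ("does not exceed").
When several groups tie for largest, the largest count is subtracted
once. Missing betas are dropped per probe before sorting; probes with
fewer than `min_samples` (default 10) observations are skipped with a
logged reason rather than scanned on too little data.

Two structural facts the test-suite verifies: the groups are exactly the
connected components of single-linkage clustering on the 1-D values cut
at the threshold (checked against a brute-force union-find oracle), and
gap-probe sets are nested as the threshold grows. The scan operates on
the beta scale because a gap width in beta units has a direct biological
reading; a threshold on M-values would not. `mvalues_to_beta`
(`2^M/(2^M+1)`) supports data delivered as M-values.

## Probe geometry conventions

Manifest coordinates are 1-based forward-strand (`c_pos` = interrogated
cytosine; the CpG guanine at `c_pos + 1`); BED-style variant tables are
0-based half-open, converted only in `gaphunt.io`. The SBE position is
`c_pos - 1` (Type I forward), `c_pos + 2` (Type I reverse — one base 5'
of the reverse-strand cytosine at `c_pos + 1`), and `c_pos` itself for
Type II. The probe footprint is taken to include the interrogated C: for
Type I the 50-mer terminates on the C (`[c_pos, c_pos + 49]` forward),
for Type II the 50-mer sits adjacent to the C with the SBE on it
(`[c_pos, c_pos + 50]` forward), both mirrored for reverse-strand
probes. Under this convention single-SNP body distances span 1..49
(Type I) and 1..50 (Type II). Variants spanning several features are
classified once with precedence C > G > SBE > body; distance is the
absolute base-pair offset from `c_pos` on the forward strand.

## SNP-to-signal rules

C/G-site outcomes are the enumerated consequences of the chemistry:
Type I probes lose all signal on any mismatch at the queried base except
the C->T change that mimics the bisulfite-converted unmethylated state;
Type II probes read the incorporated base directly (C/G dyes green, A/T
red), so forward-strand C-site changes masquerade as methylated (C->G)
or unmethylated (C->T, C->A) calls; strand reversal complements the
alleles. SBE-site outcomes are derived mechanistically: the template
base on the probed strand is bisulfite-converted (C->T) unless
methylation-protected, complemented to the incorporated base, and mapped
to its dye channel; the scanner reads only the channel the reference
base dictates, so the variant allele loses signal exactly when its
channel differs. The `sbe_methylated` flag covers the CpG-context SBE
cytosine, which conversion spares. Heterozygous readouts are the
superposition of the two per-allele outcomes; mixing is left to the
caller (the simulator models it as the dosage-weighted mean).

The copy-number metric uses the natural log; the base only rescales and
all comparisons are ratio-based. It is invariant to common rescaling of
all intensities, which the tests assert.

## Synthetic data: what it emulates, what it does not

Defaults are the study conditions of the benchmark design: 590 samples,
5000 genotype-driven gap probes (positives) and 5000 low-variance flat
probes (negatives), plus 100 "cloud" probes (genotype-correlated but
overlapping, per-dosage shift 0.08 against noise SD 0.08) and 100
outlier probes (one sample at beta 0.9 against a tight cluster at 0.05)
as labelled distractors. Genotypes are Hardy–Weinberg draws with MAF
uniform on (0.05, 0.5); the MAF floor keeps the minor groups above the
1% outlier cutoff at n = 590, mirroring the matched choice of MAF floor
and outCutoff in real-data practice. Gap probes use allele methylation
states (1.0, 0.0) — the CpG-destroying allele reads unmethylated — so
cluster means sit at 1, 0.5, 0 with truncated-Gaussian noise (SD 0.01)
on the beta scale. Separation (~0.5) versus noise (0.01) is chosen so
that recovery is guaranteed by construction; the benchmark therefore
certifies algorithmic correctness, not real-data performance.

Not emulated: dye bias, batch effects, cell-type mixture, detection
failures, imputation uncertainty, and intensity-level noise coupling —
so a perfect benchmark score says the implementation is right, not that
real 450k data will be this clean. A separate intensity-level generator
produces the body-SNP distance effect (per variant-allele copy, a linear
attenuation reaching zero effect at 50 bp, stronger in the unmethylated
channel, reflecting that channel's lower robustness to probe SNPs) for
the signal-by-distance summaries.

Truncation of beta noise at 0 and 1 produces point masses at the
boundaries, as saturated probes show in practice. This is why the GMM
baseline, although perfectly sensitive, essentially never recovers the
true component count on the benchmark (BIC prefers extra spike
components at the boundaries) — an honest reading of how fragile
mixture-model cluster counts are on beta-scale data.

## Baselines and numerical choices

The 1-D Gaussian mixture uses unequal variances, k = 1..6, five seeded
restarts per k, scikit-learn's default covariance regularisation
(1e-6), and minimum BIC (lower is better); a constant vector returns
k = 1 by convention. The dip statistic is the classical greatest-convex-
minorant / least-concave-majorant algorithm, validated against an
independent linear-programming oracle that minimises `sup|F_n - G|` over
unimodal G directly from the definition (modal jump allowed) on random
small samples. P-values are Monte-Carlo calibrated against `b_null`
(default 2000) uniform samples of the same n with the add-one
correction; the null table is memoised per (n, b_null, seed). AUC is the
rank statistic with ties at 1/2. The M-value comparison uses logit2 with
betas clamped to [1e-6, 1 - 1e-6].

The EWAS scan is plain per-probe OLS with two-sided t-tests and
Benjamini–Hochberg q-values; empirical-Bayes variance moderation is
deliberately out of scope — the contribution here is the flagging logic,
which is identical under either variance estimator, and OLS keeps the
dependency surface small. Gap-probe PCA centres probes but does not
scale them (betas share a scale); probe-mean imputation fills missing
cells before the decomposition. `flag_hits` never removes a hit: every
probe below the suggestive threshold (default 1e-4) is reported with
`is_gap`, `is_snp_annotated` and `is_outlier_driven` flags and the gap
group sizes, leaving interpretation to the analyst.

## Problem sizes

The test-suite exercises the full 5000/5000 benchmark once (about five
seconds including generation) and uses scaled-down fixtures elsewhere
(60–150 probes, 120–300 samples), sizes at which every property under
test is already decided by construction. The acceptance script
subsamples 300 probes per class for the GMM/dip baselines, which are
orders of magnitude slower than the scan itself; gap-hunting metrics are
computed on all 10,000 labelled probes. Dip calibration tests use
b_null = 500.

## Known limitations

The outlier rule keeps exactly one largest group even under ties, so a
50/50 two-group probe is never outlier-driven regardless of cutoff. The
six-way probe categorisation treats "measured" as "present in the
supplied genotype matrix" — genotype QC and imputation are upstream of
this package. Overlap assumes both inputs share a genome build;
chromosome naming is checked, builds cannot be. Full-array validation
against public 450k datasets requires external preprocessing
(normalisation, batch correction) that is out of scope here.
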