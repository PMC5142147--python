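# gaphunt

Detection and interpretation of clustered probe signals on Illumina
methylation arrays (450k / EPIC).

## The problem

A minority of array probes do not report a continuous methylation level.
Their beta values — `beta = Meth / (Meth + Unmeth + 100)` — split into two
or three discrete clusters separated by empty intervals ("gaps"). Most of
these probes sit on a polymorphism: a SNP at the interrogated cytosine, at
the CpG guanine, at the single-base-extension (SBE) site, or elsewhere in
the 50-mer changes what the probe chemistry can measure, and the beta
clusters simply track genotype. Standard QC pipelines remove probes that a
reference SNP annotation flags, but reference annotations are
population-agnostic, include irrelevant rare variants, and miss variants
private to the study sample. `gaphunt` instead finds these probes
empirically, directly from the beta matrix of the study at hand, and
supports a *flag, don't filter* workflow downstream.

## The method

**Gap hunting.** For each probe, sort the non-missing beta values
`b_(1) <= ... <= b_(n)` and compute consecutive differences
`d_i = b_(i+1) - b_(i)`. Every `d_i > threshold` (default 0.05) is a gap;
a probe with `g >= 1` gaps is a *gap signal* with `g + 1` groups, and the
gap midpoints classify samples into groups numbered in ascending beta
order. Calls where all non-largest groups together hold at most
`outCutoff * n` samples (default 1%) are *outlier-driven* and are dropped
unless explicitly retained. The scan runs on the beta scale so the
threshold maps onto biological intuition; M-values can be converted with
`beta = 2^M / (2^M + 1)`.

**SNP-to-signal rules.** `gaphunt.signal` derives, from the Infinium
chemistry (Type I vs Type II designs, strand, dye channels — C/G
fluoresce green, A/T red, bisulfite conversion), what each allele of a
SNP at the C, G, or SBE site does to the readout: mimic the methylated or
unmethylated state, abolish the signal, or leave it untouched. A
copy-number metric
`CN_i = log(Meth_i / mean(Meth_REF)) + log(Unmeth_i / mean(Unmeth_REF))`
summarises total signal against the reference-homozygous group.

**Around the core:** variant-to-probe annotation with the six-way probe
categorisation (gap status x measured SNP / annotated variant / none),
variability-filter enrichment summaries, baseline multimodality
detectors (1-D Gaussian mixture with BIC, Hartigans' dip test with a
simulated null), gap-probe principal components for population
stratification, a per-probe OLS EWAS scan with flagged hits, and a
synthetic-data generator with full ground truth.

## Worked example

```python
from gaphunt import GapHunter
from gaphunt.simulate import SimConfig, simulate_benchmark_dataset

cfg = SimConfig(n_samples=300, seed=42, n_gap_probes=40, n_flat_probes=40,
                n_cloud_probes=5, n_outlier_probes=5)
beta, truth = simulate_benchmark_dataset(cfg)
res = GapHunter(beta).fit(threshold=0.05, out_cutoff=0.01)
print(res.summary())
```

```
Gap hunting results
===================
probes scanned:      90
samples:             300
threshold:           0.05
out_cutoff:          0.01
keep_outlier_driven: False
gap probes:          40

groups  probes
     3  40
```

All 40 genotype-driven probes are called, each with three groups; the 40
flat probes, 5 overlapping "cloud" probes and 5 single-sample-outlier
probes are not (outlier-driven calls reappear, flagged, with
`keep_outlier_driven=True`). One call:

```python
call = res.call_for("gap00000")
call.n_groups, call.group_sizes, call.cutpoints
# (3, (40, 147, 113), (0.2501..., 0.7468...))
```

i.e. clusters near beta 0, 0.5 and 1 — alt-allele homozygotes,
heterozygotes and reference homozygotes of the simulated CpG-destroying
SNP — split at the two gap midpoints.

The chemistry rules are available programmatically and from the shell:

```
$ gaphunt predict --design II --strand forward --site C --ref C --alt G
ref C: unaffected, both (intact CpG; readout tracks methylation)
alt G: methylated_like, green (G reads as methylated C)

$ gaphunt predict --design I --strand forward --site SBE --ref G --alt T
ref G: unaffected, green (reference base; scanner reads this channel)
alt T: no_signal, none (fluoresces red but scanner reads green)
```

The first SNP makes a Type II probe read fully methylated regardless of
true methylation; the second silently removes one allele's signal because
the scanner only reads the channel the reference base dictates.

Other subcommands: `gaphunt hunt` (scan a beta TSV, `--grid` for the
threshold/outCutoff sensitivity grid), `simulate`, `annotate`,
`benchmark`, `pcs`, `ewas`.

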