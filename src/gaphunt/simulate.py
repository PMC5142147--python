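"""Synthetic genotype, beta, and intensity data with known ground truth.

The generator emulates the probe behaviours seen on real arrays:

* **gap probes** — a biallelic SNP destroys the CpG on one allele, so the
  per-sample mean beta is the allele-dosage-weighted mixture of the two
  allele methylation states (e.g. 1.0 / 0.0 -> clusters near 1, 0.5, 0
  for the three genotypes) with tight truncated-Gaussian noise;
* **cloud probes** — genotype-correlated but overlapping distributions
  (small allele effect, large noise), which gap hunting should NOT call;
* **outlier probes** — a single sample forms its own cluster, the
  signature of the outlier-driven rule;
* **flat probes** — low-variance unimodal negatives.

Genotypes are drawn from Hardy-Weinberg proportions at a given minor
allele frequency.  All generators are pure functions of (config, seed).

Noise is applied on the beta scale (truncated to [0, 1]); a separate
intensity-level generator produces the distance-decaying body-SNP
attenuation used for the signal-by-distance summaries, where the variant
allele attenuates intensity linearly down to nothing at distance 0 and
not at all at distance 50, more strongly in the unmethylated channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    Design,
    GenotypeMatrix,
    IntensityMatrices,
    ProbeAnnotation,
    Strand,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_gap_probe",
    "simulate_body_snp_intensities",
    "simulate_benchmark_dataset",
    "simulate_two_population_dataset",
    "benchmark_manifest",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the benchmark design of the comparison experiment:
    590 samples (the size of a realistic joint genotype+methylation
    study), 5000 genotype-driven gap probes as positive controls and
    5000 low-variance flat probes as negative controls, plus labelled
    cloud and outlier distractors.
    """

    n_samples: int = 590
    seed: int = 0
    n_gap_probes: int = 5000
    n_cloud_probes: int = 100
    n_outlier_probes: int = 100
    n_flat_probes: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    allele_meth: tuple[float, float] = (1.0, 0.0)
    noise_sd: float = 0.01
    cloud_effect: float = 0.08  # per-dosage beta shift of cloud probes
    cloud_noise_sd: float = 0.08
    flat_noise_sd: float = 0.005
    intensity_base: float = 5000.0
    intensity_cv: float = 0.1
    meth_attenuation: float = 0.5  # body-SNP max attenuation, meth channel
    unmeth_attenuation: float = 0.9  # stronger: unmeth channel less robust
    body_snp_distances: tuple[int, ...] = tuple(range(1, 51))

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for m in self.allele_meth:
            if not 0.0 <= m <= 1.0:
                raise ValidationError("allele methylation states must be in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for a synthetic dataset.

    ``table`` columns: probe_id, probe_class (gap/cloud/outlier/flat),
    true_n_groups, variant_id (empty for flat probes).
    ``genotypes`` is the generating dosage matrix;
    ``sample_groups`` maps probe_id -> per-sample true group labels
    (1..k ascending by mean beta).
    """

    table: pd.DataFrame
    genotypes: GenotypeMatrix
    sample_groups: dict[str, np.ndarray] = field(repr=False)


def simulate_genotypes(maf: float, n: int, rng) -> np.ndarray:
    """Hardy-Weinberg dosages: P(0,1,2) = ((1-p)^2, 2p(1-p), p^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValidationError(f"maf must be in (0, 0.5]: {maf}")
    rng = np.random.default_rng(rng)
    p = maf
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    return rng.choice(3, size=n, p=probs).astype(float)


def simulate_gap_probe(
    dosage: np.ndarray,
    allele_meth: tuple[float, float],
    noise_sd: float,
    rng,
) -> np.ndarray:
    """Beta values for a SNP-driven probe.

    Per-sample mean beta = (copies(allele1) * m1 + copies(allele2) * m2)/2,
    i.e. the dosage-weighted mixture of the two allele methylation states;
    Gaussian noise of SD ``noise_sd`` is added and the result clipped to
    [0, 1].
    """
    rng = np.random.default_rng(rng)
    d = np.asarray(dosage, dtype=float)
    m1, m2 = allele_meth
    mean = ((2.0 - d) * m1 + d * m2) / 2.0
    beta = mean + rng.normal(0.0, noise_sd, size=d.shape)
    return np.clip(beta, 0.0, 1.0)


def simulate_body_snp_intensities(
    dosage: np.ndarray,
    distance: int,
    config: SimConfig,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Meth/unmeth intensities for a probe with one body SNP.

    Each variant-allele copy attenuates intensity by a factor that decays
    linearly with distance from the C site: at distance 50 there is no
    effect, at distance 0 the configured maximal attenuation applies.
    The unmethylated channel is attenuated more strongly by default.
    """
    if not 1 <= distance <= 50:
        raise ValidationError("distance must be in 1..50")
    rng = np.random.default_rng(rng)
    d = np.asarray(dosage, dtype=float)
    n = d.shape[0]
    proximity = 1.0 - distance / 50.0
    base_m = config.intensity_base * rng.normal(1.0, config.intensity_cv, n).clip(0.1)
    base_u = config.intensity_base * rng.normal(1.0, config.intensity_cv, n).clip(0.1)
    # per-allele attenuation factor, averaged over the two copies
    att_m = 1.0 - config.meth_attenuation * proximity
    att_u = 1.0 - config.unmeth_attenuation * proximity
    meth = base_m * ((2.0 - d) + d * att_m) / 2.0
    unmeth = base_u * ((2.0 - d) + d * att_u) / 2.0
    return meth, unmeth


def _true_groups(dosage: np.ndarray, allele_meth: tuple[float, float]) -> np.ndarray:
    """Group labels 1..k ascending by the genotype cluster mean."""
    d = np.asarray(dosage, dtype=float)
    m1, m2 = allele_meth
    mean = ((2.0 - d) * m1 + d * m2) / 2.0
    uniq = np.unique(mean)
    return np.searchsorted(uniq, mean) + 1.0


def simulate_benchmark_dataset(config: SimConfig) -> tuple[BetaMatrix, SimTruth]:
    """The default benchmark: gap positives, flat negatives, and labelled
    cloud / outlier distractors, with full ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    truth_rows = []
    geno_rows: dict[str, np.ndarray] = {}
    groups: dict[str, np.ndarray] = {}

    def add(pid, beta, cls, n_groups, vid, grp):
        probe_ids.append(pid)
        probe_rows.append(beta)
        truth_rows.append(
            {"probe_id": pid, "probe_class": cls, "true_n_groups": n_groups,
             "variant_id": vid or ""}
        )
        groups[pid] = grp

    for i in range(config.n_gap_probes):
        pid, vid = f"gap{i:05d}", f"snp_gap{i:05d}"
        maf = rng.uniform(*config.maf_range)
        dos = simulate_genotypes(maf, n, rng)
        beta = simulate_gap_probe(dos, config.allele_meth, config.noise_sd, rng)
        grp = _true_groups(dos, config.allele_meth)
        geno_rows[vid] = dos
        add(pid, beta, "gap", int(grp.max()), vid, grp)

    for i in range(config.n_cloud_probes):
        pid, vid = f"cloud{i:05d}", f"snp_cloud{i:05d}"
        maf = rng.uniform(*config.maf_range)
        dos = simulate_genotypes(maf, n, rng)
        mean = 0.5 + config.cloud_effect * (dos - 1.0)
        beta = np.clip(mean + rng.normal(0, config.cloud_noise_sd, n), 0, 1)
        geno_rows[vid] = dos
        add(pid, beta, "cloud", 1, vid, np.ones(n))

    for i in range(config.n_outlier_probes):
        pid = f"outlier{i:05d}"
        beta = np.clip(rng.normal(0.05, config.flat_noise_sd, n), 0, 1)
        j = rng.integers(n)
        beta[j] = 0.9
        grp = np.ones(n)
        grp[j] = 2.0
        add(pid, beta, "outlier", 2, None, grp)

    for i in range(config.n_flat_probes):
        pid = f"flat{i:05d}"
        level = rng.uniform(0.0, 1.0)
        beta = np.clip(rng.normal(level, config.flat_noise_sd, n), 0, 1)
        add(pid, beta, "flat", 1, None, np.ones(n))

    beta = BetaMatrix(
        pd.DataFrame(np.vstack(probe_rows) if probe_rows else np.empty((0, n)),
                     index=probe_ids, columns=samples)
    )
    geno = GenotypeMatrix(
        dosage=pd.DataFrame(
            np.vstack(list(geno_rows.values())) if geno_rows else np.empty((0, n)),
            index=list(geno_rows), columns=samples,
        )
    )
    truth = SimTruth(
        table=pd.DataFrame(truth_rows).set_index("probe_id", drop=False)
        if truth_rows
        else pd.DataFrame(columns=["probe_id", "probe_class", "true_n_groups", "variant_id"]),
        genotypes=geno,
        sample_groups=groups,
    )
    return beta, truth


def simulate_two_population_dataset(
    n1: int,
    n2: int,
    n_probes: int,
    maf_shift: float,
    seed: int,
    noise_sd: float = 0.02,
) -> tuple[BetaMatrix, np.ndarray]:
    """Gap probes whose allele frequencies differ between two populations.

    Population 1 draws each probe's MAF from (0.05, 0.5); population 2
    uses the same frequency shifted by ``maf_shift`` (clipped to
    [0.01, 0.99] on the allele-frequency scale).  Returns the beta matrix
    and an integer population label per sample.
    """
    rng = np.random.default_rng(seed)
    n = n1 + n2
    labels = np.array([0] * n1 + [1] * n2)
    samples = [f"P{l}_{i:04d}" for i, l in enumerate(labels)]
    rows = []
    for _ in range(n_probes):
        f1 = rng.uniform(0.05, 0.5)
        f2 = float(np.clip(f1 + maf_shift, 0.01, 0.99))
        dos = np.concatenate(
            [rng.binomial(2, f1, size=n1), rng.binomial(2, f2, size=n2)]
        ).astype(float)
        rows.append(simulate_gap_probe(dos, (1.0, 0.0), noise_sd, rng))
    beta = BetaMatrix(
        pd.DataFrame(np.vstack(rows), index=[f"pp{i:05d}" for i in range(n_probes)],
                     columns=samples)
    )
    return beta, labels


def benchmark_manifest(truth: SimTruth, chrom: str = "chr1", spacing: int = 1000) -> list[ProbeAnnotation]:
    """A minimal synthetic manifest matching a benchmark dataset: probes
    laid out along one chromosome, alternating design and strand."""
    probes = []
    designs = (Design.TYPE_I, Design.TYPE_II)
    strands = (Strand.FORWARD, Strand.REVERSE)
    for i, pid in enumerate(truth.table["probe_id"]):
        design = designs[i % 2]
        probes.append(
            ProbeAnnotation(
                probe_id=pid,
                chrom=chrom,
                c_pos=(i + 1) * spacing,
                strand=strands[(i // 2) % 2],
                design=design,
                sbe_ref_base="A" if design is Design.TYPE_I else None,
            )
        )
    return probes


def attach_variant_positions(
    truth: SimTruth, probes: list[ProbeAnnotation]
) -> GenotypeMatrix:
    """Place each generating variant at its probe's C site so the
    genotype matrix carries genomic coordinates consistent with the
    synthetic manifest."""
    by_probe = {p.probe_id: p for p in probes}
    chrom, pos = {}, {}
    for row in truth.table.itertuples(index=False):
        if row.variant_id:
            p = by_probe[row.probe_id]
            chrom[row.variant_id] = p.chrom
            pos[row.variant_id] = p.c_pos
    gm = truth.genotypes
    return GenotypeMatrix(
        dosage=gm.dosage,
        ref=gm.ref,
        alt=gm.alt,
        chrom=pd.Series([chrom[v] for v in gm.variant_ids], index=gm.variant_ids),
        pos=pd.Series([pos[v] for v in gm.variant_ids], index=gm.variant_ids),
    )
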