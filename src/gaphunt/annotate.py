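"""Mapping variants and repeats onto probe geometry, probe categories,
and variability summaries.

Variants are intersected with each probe's C site, G site, SBE site and
body footprint; a variant spanning several features is classified once
with precedence C > G > SBE > body.  Probes are then partitioned into six
mutually exclusive categories crossing gap status with variant evidence:
a *measured* SNP (present in the study's genotype matrix) takes
precedence over an *annotated* variant (from a reference interval file),
which takes precedence over no variant.

Distances are absolute base-pair offsets from the interrogated C on the
forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    Design,
    GenotypeMatrix,
    IntensityMatrices,
    ProbeAnnotation,
    ValidationError,
    VariantTable,
)

__all__ = [
    "ProbeVariantOverlap",
    "overlap_probes_variants",
    "categorize_probes",
    "CATEGORIES",
    "genotype_signal_by_distance",
    "probe_sd",
    "variability_enrichment",
]

logger = logging.getLogger(__name__)

SITE_PRECEDENCE = ("C", "G", "SBE", "body")

CATEGORIES = (
    "nongap_no_variant",
    "nongap_measured_snp",
    "nongap_annotated_variant",
    "gap_no_variant",
    "gap_measured_snp",
    "gap_annotated_variant",
)


@dataclass(frozen=True)
class ProbeVariantOverlap:
    probe_id: str
    variant_id: str
    site_class: str  # C | G | SBE | body
    distance_to_c: int  # bp, 0 for the C site
    variant_class: str


def _variant_frame(variants) -> pd.DataFrame:
    """Normalise variant input to columns variant_id/chrom/start/end/class
    with 0-based half-open coordinates."""
    if isinstance(variants, VariantTable):
        return variants.data.copy()
    if isinstance(variants, GenotypeMatrix):
        if variants.chrom is None or variants.pos is None:
            raise ValidationError("GenotypeMatrix lacks chrom/pos for overlap")
        return pd.DataFrame(
            {
                "variant_id": variants.variant_ids,
                "chrom": variants.chrom.to_numpy(),
                "start": variants.pos.to_numpy(dtype=int) - 1,
                "end": variants.pos.to_numpy(dtype=int),
                "variant_class": "single",
            }
        )
    raise ValidationError(f"unsupported variant input: {type(variants).__name__}")


def overlap_probes_variants(
    probes: Sequence[ProbeAnnotation],
    variants: VariantTable | GenotypeMatrix,
) -> list[ProbeVariantOverlap]:
    """Intersect variant intervals with probe features.

    Emits one record per (probe, variant) intersection, site-classified
    with precedence C > G > SBE > body.  Both inputs must use the same
    genome build (the caller's responsibility; chromosome naming is
    checked).
    """
    vf = _variant_frame(variants)
    probe_chroms = {p.chrom for p in probes}
    var_chroms = set(vf["chrom"])
    if probes and len(vf) and not (probe_chroms & var_chroms):
        raise ValidationError(
            "no shared chromosome names between probes and variants: "
            f"probes use {sorted(probe_chroms)[:5]}, variants {sorted(var_chroms)[:5]}"
        )
    out: list[ProbeVariantOverlap] = []
    by_chrom = {c: g for c, g in vf.groupby("chrom", sort=False)}
    for p in probes:
        g = by_chrom.get(p.chrom)
        if g is None:
            continue
        lo, hi = p.body_interval  # 1-based inclusive
        if p.design is Design.TYPE_I:
            # the Type I SBE base sits just outside the 50-mer footprint
            lo, hi = min(lo, p.sbe_pos), max(hi, p.sbe_pos)
        start = g["start"].to_numpy()  # 0-based half-open
        end = g["end"].to_numpy()
        hit = (start < hi) & (end > lo - 1)
        if not hit.any():
            continue
        for row in g.loc[hit].itertuples(index=False):
            site = _classify_site(p, row.start, row.end)
            pos1 = row.start + 1  # nearest 1-based position for distance
            # distance from the C site to the closest covered base
            if row.start + 1 <= p.c_pos <= row.end:
                dist = 0
            else:
                dist = min(abs(pos1 - p.c_pos), abs(row.end - p.c_pos))
            out.append(
                ProbeVariantOverlap(
                    probe_id=p.probe_id,
                    variant_id=row.variant_id,
                    site_class=site,
                    distance_to_c=int(dist),
                    variant_class=row.variant_class,
                )
            )
    return out


def _classify_site(p: ProbeAnnotation, start: int, end: int) -> str:
    """Site class for a 0-based half-open variant interval on probe ``p``."""
    def covers(pos: int) -> bool:  # pos is 1-based
        return start + 1 <= pos <= end

    if covers(p.c_pos):
        return "C"
    if covers(p.g_pos):
        return "G"
    if p.design is Design.TYPE_I and covers(p.sbe_pos):
        return "SBE"
    return "body"


def categorize_probes(
    all_probe_ids: Iterable[str],
    gap_ids: Iterable[str],
    measured_overlaps: Iterable[ProbeVariantOverlap],
    annotated_overlaps: Iterable[ProbeVariantOverlap],
) -> pd.Series:
    """Partition probes into the six gap x variant-evidence categories.

    Returns a Series indexed by probe id with values from
    :data:`CATEGORIES`.
    """
    all_ids = pd.Index(list(all_probe_ids))
    gap = set(gap_ids)
    unknown = gap - set(all_ids)
    if unknown:
        raise ValidationError(f"gap ids not in probe universe: {sorted(unknown)[:5]}")
    measured = {o.probe_id for o in measured_overlaps}
    annotated = {o.probe_id for o in annotated_overlaps}
    cats = []
    for pid in all_ids:
        prefix = "gap" if pid in gap else "nongap"
        if pid in measured:
            cats.append(f"{prefix}_measured_snp")
        elif pid in annotated:
            cats.append(f"{prefix}_annotated_variant")
        else:
            cats.append(f"{prefix}_no_variant")
    return pd.Series(cats, index=all_ids, name="category")


def genotype_signal_by_distance(
    intensities: IntensityMatrices,
    genotypes: GenotypeMatrix,
    overlaps: Iterable[ProbeVariantOverlap],
    design: Design,
    probes: Sequence[ProbeAnnotation] | None = None,
) -> pd.DataFrame:
    """Mean and IQR of channel intensity by SNP distance and genotype group.

    Restricted to probes with exactly one body-class overlap and no
    C/G/SBE overlap, so the distance effect of a single probe SNP is
    isolated.  Returns a long-format frame with columns distance,
    genotype (ref_hom / het / alt_hom), channel (meth / unmeth), mean,
    q25, q75, n_probes.
    """
    per_probe: dict[str, list[ProbeVariantOverlap]] = {}
    for o in overlaps:
        per_probe.setdefault(o.probe_id, []).append(o)
    design_ids = None
    if probes is not None:
        design_ids = {p.probe_id for p in probes if p.design is design}
    eligible: list[tuple[str, str, int]] = []
    for pid, ovs in per_probe.items():
        if design_ids is not None and pid not in design_ids:
            continue
        if len(ovs) != 1 or ovs[0].site_class != "body":
            continue
        o = ovs[0]
        if o.variant_id not in genotypes.variant_ids or pid not in intensities.probe_ids:
            continue
        eligible.append((pid, o.variant_id, o.distance_to_c))
    if not eligible:
        logger.warning("genotype_signal_by_distance: no qualifying probes")
        return pd.DataFrame(
            columns=["distance", "genotype", "channel", "mean", "q25", "q75", "n_probes"]
        )
    groups = {"ref_hom": 0.0, "het": 1.0, "alt_hom": 2.0}
    rows = []
    by_distance: dict[int, list[tuple[str, str]]] = {}
    for pid, vid, dist in eligible:
        by_distance.setdefault(dist, []).append((pid, vid))
    for dist in sorted(by_distance):
        pairs = by_distance[dist]
        for channel, mat in (("meth", intensities.meth), ("unmeth", intensities.unmeth)):
            pooled: dict[str, list[np.ndarray]] = {g: [] for g in groups}
            for pid, vid in pairs:
                x = mat.loc[pid].to_numpy(dtype=float)
                d = genotypes.dosage.loc[vid].reindex(mat.columns).to_numpy(dtype=float)
                for gname, dval in groups.items():
                    sel = x[d == dval]
                    if sel.size:
                        pooled[gname].append(sel)
            for gname, chunks in pooled.items():
                if not chunks:
                    continue
                allv = np.concatenate(chunks)
                rows.append(
                    {
                        "distance": dist,
                        "genotype": gname,
                        "channel": channel,
                        "mean": float(allv.mean()),
                        "q25": float(np.percentile(allv, 25)),
                        "q75": float(np.percentile(allv, 75)),
                        "n_probes": len(pairs),
                    }
                )
    return pd.DataFrame(rows)


def probe_sd(beta: BetaMatrix) -> pd.Series:
    """Per-probe sample standard deviation (n-1 denominator), ignoring
    missing values; probes with fewer than 2 observations get NaN."""
    vals = beta.values()
    n_obs = np.sum(~np.isnan(vals), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.array([np.nanstd(row, ddof=1) if n >= 2 else np.nan
                       for row, n in zip(vals, n_obs)])
    n_bad = int((n_obs < 2).sum())
    if n_bad:
        logger.warning("probe_sd: %d probes with <2 observations -> NaN", n_bad)
    return pd.Series(sd, index=beta.probe_ids, name="sd")


def variability_enrichment(
    sd: pd.Series,
    gap_ids: Iterable[str],
    percentile_cutoffs: Sequence[float] | None = None,
    interpolation: str = "linear",
) -> pd.DataFrame:
    """Gap-probe enrichment under variably-methylated-probe filtering.

    For each percentile cutoff, retain probes whose SD exceeds that
    percentile of all SDs and report the retained count and the fraction
    of retained probes that are gap signals.  Default cutoff grid: 0 and
    5..99.
    """
    if percentile_cutoffs is None:
        percentile_cutoffs = [0] + list(range(5, 100))
    bad = [c for c in percentile_cutoffs if not 0 <= c < 100]
    if bad:
        raise ValidationError(f"percentile cutoffs must lie in [0, 100): {bad}")
    sd = sd.dropna()
    gap = set(gap_ids)
    is_gap = sd.index.isin(gap)
    rows = []
    for cut in percentile_cutoffs:
        if cut == 0:
            keep = np.ones(len(sd), dtype=bool)
        else:
            thr = np.percentile(sd.to_numpy(), cut, method=interpolation)
            keep = sd.to_numpy() > thr
        n = int(keep.sum())
        frac = float(is_gap[keep].mean()) if n else np.nan
        rows.append({"cutoff_percentile": cut, "retained": n, "gap_fraction": frac})
    return pd.DataFrame(rows)
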