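"""Readers and writers for every on-disk format the tool touches.

All other modules operate on the in-memory types from
:mod:`gaphunt.datatypes`; parsing, validation, and coordinate conversion
(1-based manifest vs 0-based half-open BED) are centralised here.

Beta matrices and gap-call tables round-trip at 6 decimal places.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BETA_TOL,
    BetaMatrix,
    Design,
    GapCall,
    GenotypeMatrix,
    IntensityMatrices,
    ProbeAnnotation,
    Strand,
    ValidationError,
    VariantTable,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_intensities",
    "read_manifest",
    "write_manifest",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_variant_table",
    "write_gap_calls",
    "read_gap_calls",
]

FLOAT_FMT = "%.6f"


def _read_matrix_tsv(path: str | os.PathLike, missing_token: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        dtype=str,
    )
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}: "
                f"{df.loc[probe, col]!r}"
            )
        out[col] = converted.to_numpy()
    return out


def read_beta_matrix(path: str | os.PathLike, missing_token: str = "NA") -> BetaMatrix:
    """Read a probes x samples beta-value TSV.

    The first column holds probe ids, the header row sample ids.  Cells equal
    to ``missing_token`` become missing values.  Values outside [0, 1] (beyond
    a 1e-9 tolerance) raise :class:`ValidationError` naming probe and sample.
    """
    return BetaMatrix(_read_matrix_tsv(path, missing_token))


def write_beta_matrix(
    beta: BetaMatrix, path: str | os.PathLike, missing_token: str = "NA"
) -> str:
    beta.data.to_csv(
        path, sep="\t", na_rep=missing_token, float_format=FLOAT_FMT, index_label="probe_id"
    )
    return os.fspath(path)


def read_intensities(
    meth_path: str | os.PathLike,
    unmeth_path: str | os.PathLike,
    missing_token: str = "NA",
) -> IntensityMatrices:
    """Read paired methylated / unmethylated intensity TSVs."""
    return IntensityMatrices(
        meth=_read_matrix_tsv(meth_path, missing_token),
        unmeth=_read_matrix_tsv(unmeth_path, missing_token),
    )


MANIFEST_COLUMNS = ["probe_id", "chrom", "c_pos", "strand", "design", "sbe_ref_base"]


def read_manifest(path: str | os.PathLike) -> list[ProbeAnnotation]:
    """Read a probe manifest CSV (columns: probe_id, chrom, c_pos, strand,
    design, sbe_ref_base; the last blank for Type II probes)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    probes = []
    for row in df.itertuples(index=False):
        sbe = row.sbe_ref_base.strip() or None
        probes.append(
            ProbeAnnotation(
                probe_id=row.probe_id,
                chrom=row.chrom,
                c_pos=int(row.c_pos),
                strand=Strand.parse(row.strand),
                design=Design.parse(row.design),
                sbe_ref_base=sbe,
            )
        )
    ids = pd.Index([p.probe_id for p in probes])
    if ids.has_duplicates:
        raise ValidationError(f"{path}: duplicate probe ids in manifest")
    return probes


def write_manifest(probes: Iterable[ProbeAnnotation], path: str | os.PathLike) -> str:
    rows = [
        {
            "probe_id": p.probe_id,
            "chrom": p.chrom,
            "c_pos": p.c_pos,
            "strand": p.strand.value,
            "design": p.design.value,
            "sbe_ref_base": p.sbe_ref_base or "",
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return os.fspath(path)


def _read_genotypes_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    ids, refs, alts, chroms, poss, rows = [], [], [], [], [], []
    rejected = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            rejected.append((rec.ID or f"{rec.CHROM}:{rec.POS}", "multi-allelic"))
            continue
        # gts012: 0/1/2 = alt-allele count, 3 = missing
        gt = np.asarray(rec.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        rows.append(gt)
    dosage = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(ids), len(samples)),
        index=pd.Index(ids, name="variant_id"),
        columns=samples,
    )
    gm = GenotypeMatrix(
        dosage=dosage,
        ref=pd.Series(refs, index=dosage.index),
        alt=pd.Series(alts, index=dosage.index),
        chrom=pd.Series(chroms, index=dosage.index),
        pos=pd.Series(poss, index=dosage.index),
    )
    # rejected records are reported, never silently dropped
    gm = gm  # noqa: PLW0127
    object.__setattr__(gm, "rejected", tuple(rejected))
    return gm


GENOTYPE_META = ["chrom", "pos", "ref", "alt"]


def _read_genotypes_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    meta = {}
    for col in GENOTYPE_META:
        if col in df.columns:
            meta[col] = df.pop(col)
    dosage = df.astype(float)
    gm = GenotypeMatrix(
        dosage=dosage,
        ref=meta.get("ref"),
        alt=meta.get("alt"),
        chrom=meta.get("chrom"),
        pos=meta.get("pos").astype(int) if "pos" in meta else None,
    )
    object.__setattr__(gm, "rejected", ())
    return gm


def read_genotypes(path: str | os.PathLike, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field, bi-allelic records only) or a
    dosage TSV (first column variant id, optional chrom/pos/ref/alt columns,
    remaining columns per-sample alt-allele counts).

    Multi-allelic VCF records are rejected and listed on the returned
    object's ``rejected`` attribute as (variant, reason) pairs.
    """
    if format == "auto":
        format = "vcf" if os.fspath(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValidationError(f"unknown genotype format: {format!r}")


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | os.PathLike) -> str:
    df = gm.dosage.copy()
    for col in reversed(GENOTYPE_META):
        series = getattr(gm, col)
        if series is not None:
            df.insert(0, col, series)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="variant_id")
    return os.fspath(path)


def read_variant_table(path: str | os.PathLike) -> VariantTable:
    """Read a BED3+name+class file: chrom, start, end (0-based half-open),
    variant_id, variant_class.  No header line."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "variant_id", "variant_class"],
        dtype={"chrom": str, "start": int, "end": int, "variant_id": str, "variant_class": str},
    )
    return VariantTable(df[["variant_id", "chrom", "start", "end", "variant_class"]])


GAP_CALL_COLUMNS = ["probe_id", "n_groups", "group_sizes", "cutpoints", "outlier_driven"]


def write_gap_calls(
    calls: Sequence[GapCall],
    path: str | os.PathLike,
    sample_ids: Sequence[str] | None = None,
    labels_path: str | os.PathLike | None = None,
) -> str:
    """Write gap calls as TSV; optionally a companion per-sample label TSV.

    ``group_sizes`` and ``cutpoints`` are comma-joined in ascending beta
    order; ``outlier_driven`` is 0/1.
    """
    rows = [
        {
            "probe_id": c.probe_id,
            "n_groups": c.n_groups,
            "group_sizes": ",".join(str(s) for s in c.group_sizes),
            "cutpoints": ",".join(FLOAT_FMT % x for x in c.cutpoints),
            "outlier_driven": int(c.outlier_driven),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=GAP_CALL_COLUMNS).to_csv(path, sep="\t", index=False)
    if labels_path is not None:
        if sample_ids is None:
            raise ValidationError("labels_path requires sample_ids")
        lab = pd.DataFrame(
            {c.probe_id: pd.array(c.sample_groups, dtype="Int64") for c in calls},
            index=pd.Index(sample_ids, name="sample_id"),
        ).T
        lab.index.name = "probe_id"
        lab.to_csv(labels_path, sep="\t", na_rep="NA")
    return os.fspath(path)


def read_gap_calls(
    path: str | os.PathLike, labels_path: str | os.PathLike | None = None
) -> list[GapCall]:
    """Inverse of :func:`write_gap_calls` (up to 6-decimal float formatting).

    Without a labels file, per-sample group labels are reconstructed as a
    flat expansion consistent with the stored group sizes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(
            labels_path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
        )
    calls = []
    for row in df.itertuples(index=False):
        sizes = tuple(int(s) for s in row.group_sizes.split(",") if s != "")
        cuts = tuple(float(s) for s in row.cutpoints.split(",") if s != "")
        if labels is not None:
            sg = labels.loc[row.probe_id].to_numpy(dtype=float)
        else:
            sg = np.repeat(np.arange(1, len(sizes) + 1, dtype=float), sizes)
        calls.append(
            GapCall(
                probe_id=row.probe_id,
                n_groups=int(row.n_groups),
                group_sizes=sizes,
                cutpoints=cuts,
                sample_groups=sg,
                outlier_driven=bool(int(row.outlier_driven)),
            )
        )
    return calls
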