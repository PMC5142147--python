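"""Core domain types shared across the package.

Coordinate conventions
----------------------
Probe manifests use 1-based inclusive genomic coordinates on the forward
strand (the Illumina MAPINFO convention): ``c_pos`` is the position of the
interrogated cytosine, the CpG guanine sits at ``c_pos + 1``.  Interval
files (BED-style variant/repeat tables) are 0-based half-open; conversion
happens in :mod:`gaphunt.io` and nowhere else.

The single-base-extension (SBE) position is derived from probe geometry:
Type I probes extend one base 5' of the interrogated C (``c_pos - 1`` for
forward-strand probes, ``c_pos + 2`` for reverse-strand probes, where the
reverse-strand cytosine sits at forward coordinate ``c_pos + 1``); for
Type II probes the SBE coincides with the C site.

The probe footprint ("body") always contains the interrogated C.  For
Type I the 50-mer terminates on the C itself, so body SNP distances run
1..49; for Type II the 50-mer sits adjacent to the C (the SBE base), so
distances run 1..50.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Strand",
    "Design",
    "BetaMatrix",
    "IntensityMatrices",
    "ProbeAnnotation",
    "GenotypeMatrix",
    "VariantTable",
    "GapCall",
    "ValidationError",
    "BETA_TOL",
]

#: Slack allowed when checking that beta values lie in [0, 1].
BETA_TOL = 1e-9

VARIANT_CLASSES = frozenset(
    {"single", "mnp", "indel", "microsatellite", "range", "repeat"}
)


class ValidationError(ValueError):
    """Raised when an on-disk or in-memory object violates its contract."""


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"

    @classmethod
    def parse(cls, token: str) -> "Strand":
        t = str(token).strip().lower()
        if t in {"forward", "f", "+"}:
            return cls.FORWARD
        if t in {"reverse", "r", "-"}:
            return cls.REVERSE
        raise ValidationError(f"unknown strand code: {token!r}")


class Design(str, enum.Enum):
    TYPE_I = "I"
    TYPE_II = "II"

    @classmethod
    def parse(cls, token: str) -> "Design":
        t = str(token).strip().upper()
        if t in {"I", "TYPEI", "TYPE_I", "1"}:
            return cls.TYPE_I
        if t in {"II", "TYPEII", "TYPE_II", "2"}:
            return cls.TYPE_II
        raise ValidationError(f"unknown probe design code: {token!r}")


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Parameters
    ----------
    data
        ``pandas.DataFrame`` with probe ids as the index and sample ids as
        columns.  Missing values are ``NaN``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe id")
        _check_unique(self.data.columns, "sample id")
        vals = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < -BETA_TOL) | (vals > 1.0 + BETA_TOL)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"unknown probe ids: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probe_ids)])


@dataclass(frozen=True)
class IntensityMatrices:
    """Paired methylated / unmethylated fluorescence intensity matrices."""

    meth: pd.DataFrame
    unmeth: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise ValidationError("meth and unmeth shapes differ")
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValidationError("meth and unmeth ids differ")
        for name, df in (("meth", self.meth), ("unmeth", self.unmeth)):
            vals = df.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if (vals < 0).any():
                    raise ValidationError(f"negative intensity in {name} matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    def beta(self, offset: float = 100.0) -> BetaMatrix:
        """Beta values: meth / (meth + unmeth + offset)."""
        m = self.meth.to_numpy(dtype=float)
        u = self.unmeth.to_numpy(dtype=float)
        b = m / (m + u + offset)
        return BetaMatrix(pd.DataFrame(b, index=self.probe_ids, columns=self.sample_ids))


#: length of the probe oligo in bases
PROBE_LENGTH = 50


@dataclass(frozen=True)
class ProbeAnnotation:
    """Geometry of one array probe in forward-strand coordinates."""

    probe_id: str
    chrom: str
    c_pos: int  # 1-based, forward strand
    strand: Strand
    design: Design
    sbe_ref_base: str | None = None  # Type I only

    def __post_init__(self) -> None:
        if self.design is Design.TYPE_I:
            if self.sbe_ref_base not in {"A", "C", "G", "T"}:
                raise ValidationError(
                    f"{self.probe_id}: Type I probe requires an SBE reference base, "
                    f"got {self.sbe_ref_base!r}"
                )
        elif self.sbe_ref_base not in (None, ""):
            raise ValidationError(
                f"{self.probe_id}: Type II probe must not carry an SBE reference base"
            )

    @property
    def g_pos(self) -> int:
        """Forward-strand position of the CpG guanine."""
        return self.c_pos + 1

    @property
    def sbe_pos(self) -> int:
        if self.design is Design.TYPE_II:
            return self.c_pos
        if self.strand is Strand.FORWARD:
            return self.c_pos - 1
        return self.c_pos + 2

    @property
    def body_interval(self) -> tuple[int, int]:
        """1-based inclusive footprint of the probe; always contains c_pos."""
        if self.design is Design.TYPE_I:
            if self.strand is Strand.FORWARD:
                return (self.c_pos, self.c_pos + PROBE_LENGTH - 1)
            return (self.c_pos - PROBE_LENGTH + 2, self.c_pos + 1)
        if self.strand is Strand.FORWARD:
            return (self.c_pos, self.c_pos + PROBE_LENGTH)
        return (self.c_pos - PROBE_LENGTH, self.c_pos + 1)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Variants x samples dosage matrix (count of the non-reference allele).

    ``dosage`` holds values in {0, 1, 2} with NaN for missing calls.
    """

    dosage: pd.DataFrame
    ref: pd.Series = field(default=None)  # type: ignore[assignment]
    alt: pd.Series = field(default=None)  # type: ignore[assignment]
    chrom: pd.Series = field(default=None)  # type: ignore[assignment]
    pos: pd.Series = field(default=None)  # type: ignore[assignment]  # 1-based

    def __post_init__(self) -> None:
        _check_unique(self.dosage.index, "variant id")
        _check_unique(self.dosage.columns, "sample id")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"dosage not in {{0,1,2}} at {self.dosage.index[i]!r}/"
                f"{self.dosage.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.columns

    def maf(self) -> pd.Series:
        """Minor allele frequency from observed (non-missing) alleles."""
        vals = self.dosage.to_numpy(dtype=float)
        n_called = np.sum(~np.isnan(vals), axis=1)
        alt_freq = np.nansum(vals, axis=1) / np.maximum(2 * n_called, 1)
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
        maf[n_called == 0] = np.nan
        return pd.Series(maf, index=self.variant_ids, name="maf")


@dataclass(frozen=True)
class VariantTable:
    """Annotated variant / repeat intervals, 0-based half-open.

    ``data`` columns: variant_id, chrom, start, end, variant_class.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variant_id", "chrom", "start", "end", "variant_class"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"variant table missing columns: {sorted(missing)}")
        _check_unique(pd.Index(self.data["variant_id"]), "variant id")
        bad_class = set(self.data["variant_class"]) - VARIANT_CLASSES
        if bad_class:
            raise ValidationError(f"unknown variant classes: {sorted(bad_class)}")
        start = self.data["start"].to_numpy()
        end = self.data["end"].to_numpy()
        if (start >= end).any():
            raise ValidationError("variant interval with start >= end")
        single = self.data["variant_class"].to_numpy() == "single"
        if ((end - start) != 1)[single].any():
            raise ValidationError("variant of class 'single' must span one base")


@dataclass(frozen=True)
class GapCall:
    """Cluster structure of one gap-signal probe.

    Groups are numbered 1..n_groups in ascending beta order; ``sample_groups``
    aligns with the beta matrix sample order and is NaN for missing betas.
    """

    probe_id: str
    n_groups: int
    group_sizes: tuple[int, ...]
    cutpoints: tuple[float, ...]
    sample_groups: np.ndarray  # float array, NaN = missing
    outlier_driven: bool

    def __post_init__(self) -> None:
        if self.n_groups != len(self.cutpoints) + 1:
            raise ValidationError(
                f"{self.probe_id}: n_groups must equal number of cutpoints + 1"
            )
        if self.n_groups != len(self.group_sizes):
            raise ValidationError(f"{self.probe_id}: group_sizes length mismatch")
        labels = np.asarray(self.sample_groups, dtype=float)
        observed = labels[~np.isnan(labels)]
        if len(observed) != sum(self.group_sizes):
            raise ValidationError(
                f"{self.probe_id}: group sizes do not sum to non-missing samples"
            )
        counts = np.bincount(observed.astype(int), minlength=self.n_groups + 1)[1:]
        if tuple(counts) != tuple(self.group_sizes):
            raise ValidationError(f"{self.probe_id}: labels inconsistent with sizes")
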