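"""Mechanistic prediction of Infinium probe signal under SNPs.

The array chemistry constrains what a SNP at the interrogated cytosine
(C site), the CpG guanine (G site), or the single-base-extension (SBE)
site can do to the fluorescent readout:

* Type I probes use two bead types (methylated / unmethylated sequence)
  read in one colour channel; a mismatch at the queried base abolishes
  extension, so most C/G-site SNPs give no signal at all, while a C->T
  change mimics the bisulfite-converted unmethylated state.
* Type II probes read the incorporated base directly in two colours
  (C/G bases fluoresce green, A/T red), so C-site SNPs on the forward
  strand masquerade as methylated (green, C->G) or unmethylated (red,
  C->T / C->A) calls.
* At a Type I SBE site the scanner only reads the colour channel the
  reference base dictates; an allele whose incorporated base fluoresces
  in the other channel is simply not read (signal loss), while an allele
  in the same channel leaves the readout untouched.

All alleles are expressed on the forward genomic strand; reverse-strand
probes complement internally.  SBE template bases are bisulfite-converted
(C -> T) assuming the base is an unmethylated, non-CpG cytosine; set
``sbe_methylated=True`` for a CpG-context SBE cytosine that is protected
from conversion.

A copy-number style summary of total signal per sample is also provided:
``CN_i = ln(Meth_i / mean(Meth_REF)) + ln(Unmeth_i / mean(Unmeth_REF))``
with the reference means taken over reference-homozygous samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Design, Strand, ValidationError

__all__ = [
    "Site",
    "Outcome",
    "Channel",
    "SnpScenario",
    "AllelePrediction",
    "SignalPrediction",
    "expected_channel",
    "predict_cpg_snp",
    "predict_sbe_snp",
    "predict",
    "copy_number",
    "enumerate_rule_tables",
]

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Site(str, enum.Enum):
    C = "C"
    G = "G"
    SBE = "SBE"


class Outcome(str, enum.Enum):
    METHYLATED_LIKE = "methylated_like"
    UNMETHYLATED_LIKE = "unmethylated_like"
    NO_SIGNAL = "no_signal"
    UNAFFECTED = "unaffected"


class Channel(str, enum.Enum):
    RED = "red"
    GREEN = "green"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class SnpScenario:
    """One SNP scenario: probe design, strand, affected site, allele pair.

    ``ref_base`` / ``alt_base`` are the reference-genome and variant bases
    at the affected position, written on the forward strand.
    """

    design: Design
    strand: Strand
    site: Site
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        for b in (self.ref_base, self.alt_base):
            if b not in BASES:
                raise ValidationError(f"invalid base: {b!r}")
        if self.ref_base == self.alt_base:
            raise ValidationError("ref and alt bases must differ")
        if self.site is Site.SBE and self.design is Design.TYPE_II:
            raise ValidationError(
                "Type II SBE coincides with the C site; use site=C"
            )


@dataclass(frozen=True)
class AllelePrediction:
    outcome: Outcome
    channel: Channel
    note: str = ""


@dataclass(frozen=True)
class SignalPrediction:
    """Per-allele expected readout for one scenario."""

    scenario: SnpScenario
    ref: AllelePrediction
    alt: AllelePrediction

    def __post_init__(self) -> None:
        for p in (self.ref, self.alt):
            if (p.outcome is Outcome.NO_SIGNAL) != (p.channel is Channel.NONE):
                raise ValidationError("no_signal iff channel none")


def expected_channel(base: str) -> Channel:
    """Colour channel of the dye coupled to an incorporated base:
    C and G fluoresce green, A and T red."""
    if base in ("C", "G"):
        return Channel.GREEN
    if base in ("A", "T"):
        return Channel.RED
    raise ValidationError(f"invalid base: {base!r}")


def _cpg_alt_outcome(scenario: SnpScenario) -> tuple[Outcome, Channel, str]:
    """Enumerated C/G-site rules (alt allele; the reference allele behaves
    as an ordinary CpG and is reported with channel 'both')."""
    design, strand, site = scenario.design, scenario.strand, scenario.site
    alt = scenario.alt_base
    if site is Site.C:
        if scenario.ref_base != "C":
            raise ValidationError("C-site scenarios must have ref_base C")
        if strand is Strand.REVERSE:
            # probe interrogates the reverse strand; losing the forward C
            # destroys the reverse-strand G template needed for extension
            return Outcome.NO_SIGNAL, Channel.NONE, "reverse-strand C-site SNP"
        if design is Design.TYPE_I:
            if alt == "T":
                return (
                    Outcome.UNMETHYLATED_LIKE,
                    Channel.BOTH,
                    "T mimics the bisulfite-converted unmethylated C",
                )
            return Outcome.NO_SIGNAL, Channel.NONE, "mismatch abolishes extension"
        # Type II forward: the incorporated base is read directly
        if alt == "G":
            return Outcome.METHYLATED_LIKE, Channel.GREEN, "G reads as methylated C"
        return Outcome.UNMETHYLATED_LIKE, Channel.RED, f"{alt} reads as unmethylated"
    # G site
    if scenario.ref_base != "G":
        raise ValidationError("G-site scenarios must have ref_base G")
    if strand is Strand.FORWARD:
        return Outcome.NO_SIGNAL, Channel.NONE, "forward-strand G-site SNP blocks SBE"
    # reverse-strand probes read the G site as their own C; complement the
    # forward-strand alleles to reuse the forward C-site logic
    comp = COMPLEMENT[alt]
    if design is Design.TYPE_I:
        if comp == "T":  # alt A on the forward strand
            return Outcome.UNMETHYLATED_LIKE, Channel.BOTH, "A complements converted T"
        return Outcome.NO_SIGNAL, Channel.NONE, "mismatch abolishes extension"
    if comp == "G":  # alt C on the forward strand
        return Outcome.METHYLATED_LIKE, Channel.GREEN, "C complements methylated-like G"
    return Outcome.UNMETHYLATED_LIKE, Channel.RED, f"{alt} reads as unmethylated"


def predict_cpg_snp(scenario: SnpScenario) -> SignalPrediction:
    """Predict the readout for a SNP at the interrogated C or G site."""
    if scenario.site is Site.SBE:
        raise ValidationError("use predict_sbe_snp for SBE-site scenarios")
    outcome, channel, note = _cpg_alt_outcome(scenario)
    # reference allele: an intact CpG, readout tracks true methylation
    ref = AllelePrediction(
        Outcome.UNAFFECTED, Channel.BOTH, "intact CpG; readout tracks methylation"
    )
    return SignalPrediction(scenario, ref=ref, alt=AllelePrediction(outcome, channel, note))


def _sbe_channel(forward_base: str, strand: Strand, sbe_methylated: bool) -> Channel:
    """Channel in which a given SBE-position allele fluoresces.

    The template strand is the probed strand; its base is bisulfite
    converted (C -> T) unless protected by methylation, and the
    incorporated base is the complement of the converted template.
    """
    template = forward_base if strand is Strand.FORWARD else COMPLEMENT[forward_base]
    if template == "C" and not sbe_methylated:
        template = "T"
    incorporated = COMPLEMENT[template]
    return expected_channel(incorporated)


def predict_sbe_snp(scenario: SnpScenario, sbe_methylated: bool = False) -> SignalPrediction:
    """Predict the readout for a SNP at a Type I SBE site.

    The scanner reads only the channel dictated by the reference base, so
    the variant allele loses signal exactly when its incorporated base
    fluoresces in the other channel; otherwise the readout is unaffected.
    """
    if scenario.design is not Design.TYPE_I:
        raise ValidationError("SBE-site scenarios apply to Type I probes only")
    if scenario.site is not Site.SBE:
        raise ValidationError("predict_sbe_snp requires site=SBE")
    ref_ch = _sbe_channel(scenario.ref_base, scenario.strand, sbe_methylated)
    alt_ch = _sbe_channel(scenario.alt_base, scenario.strand, sbe_methylated)
    ref = AllelePrediction(
        Outcome.UNAFFECTED, ref_ch, "reference base; scanner reads this channel"
    )
    if alt_ch is ref_ch:
        alt = AllelePrediction(
            Outcome.UNAFFECTED, alt_ch, "same channel as reference; readout intact"
        )
    else:
        alt = AllelePrediction(
            Outcome.NO_SIGNAL,
            Channel.NONE,
            f"fluoresces {alt_ch.value} but scanner reads {ref_ch.value}",
        )
    return SignalPrediction(scenario, ref=ref, alt=alt)


def predict(scenario: SnpScenario, sbe_methylated: bool = False) -> SignalPrediction:
    """Dispatch to the C/G-site or SBE-site rules."""
    if scenario.site is Site.SBE:
        return predict_sbe_snp(scenario, sbe_methylated=sbe_methylated)
    return predict_cpg_snp(scenario)


def copy_number(
    meth: np.ndarray,
    unmeth: np.ndarray,
    ref_mask: np.ndarray,
) -> np.ndarray:
    """Per-sample copy-number metric.

    ``CN_i = ln(Meth_i / mean Meth_REF) + ln(Unmeth_i / mean Unmeth_REF)``,
    the reference means taken over ``ref_mask`` (reference-homozygous
    samples).  Natural log; any common rescaling of all intensities
    cancels.
    """
    m = np.asarray(meth, dtype=float)
    u = np.asarray(unmeth, dtype=float)
    mask = np.asarray(ref_mask, dtype=bool)
    if m.shape != u.shape or mask.shape != m.shape:
        raise ValidationError("meth, unmeth and ref_mask must share a shape")
    if not mask.any():
        raise ValidationError("ref_mask selects no samples")
    if (m <= 0).any() or (u <= 0).any():
        raise ValidationError("intensities must be strictly positive")
    return np.log(m / m[mask].mean()) + np.log(u / u[mask].mean())


def enumerate_rule_tables(sbe_methylated: bool = False) -> pd.DataFrame:
    """Full prediction table over every valid scenario.

    C/G-site scenarios: 2 designs x 2 strands x 2 sites x 3 variant bases
    (ref fixed by the site) = 24 rows.  SBE scenarios: Type I only,
    2 strands x 4 ref x 3 alt = 24 rows.  One row per allele outcome pair.
    """
    rows = []
    for design in Design:
        for strand in Strand:
            for site in (Site.C, Site.G):
                ref = "C" if site is Site.C else "G"
                for alt in BASES:
                    if alt == ref:
                        continue
                    sc = SnpScenario(design, strand, site, ref, alt)
                    pred = predict_cpg_snp(sc)
                    rows.append(_row(sc, pred))
    for strand in Strand:
        for ref in BASES:
            for alt in BASES:
                if alt == ref:
                    continue
                sc = SnpScenario(Design.TYPE_I, strand, Site.SBE, ref, alt)
                pred = predict_sbe_snp(sc, sbe_methylated=sbe_methylated)
                rows.append(_row(sc, pred))
    return pd.DataFrame(rows)


def _row(sc: SnpScenario, pred: SignalPrediction) -> dict:
    return {
        "design": sc.design.value,
        "strand": sc.strand.value,
        "site": sc.site.value,
        "ref": sc.ref_base,
        "alt": sc.alt_base,
        "ref_outcome": pred.ref.outcome.value,
        "ref_channel": pred.ref.channel.value,
        "alt_outcome": pred.alt.outcome.value,
        "alt_channel": pred.alt.channel.value,
        "note": pred.alt.note,
    }
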