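import numpy as np
import pandas as pd
import pytest

from gaphunt.annotate import (
    CATEGORIES,
    ProbeVariantOverlap,
    categorize_probes,
    genotype_signal_by_distance,
    overlap_probes_variants,
    probe_sd,
    variability_enrichment,
)
from gaphunt.datatypes import (
    BetaMatrix,
    Design,
    GenotypeMatrix,
    IntensityMatrices,
    ProbeAnnotation,
    Strand,
    ValidationError,
    VariantTable,
)
from gaphunt.simulate import SimConfig, simulate_body_snp_intensities, simulate_genotypes


def _probe(pid="p1", c_pos=1000, strand=Strand.FORWARD, design=Design.TYPE_I):
    return ProbeAnnotation(pid, "chr1", c_pos, strand, design,
                           "A" if design is Design.TYPE_I else None)


def _vt(rows):
    return VariantTable(pd.DataFrame(rows,
                                     columns=["variant_id", "chrom", "start", "end",
                                              "variant_class"]))


class TestOverlap:
    def test_site_classes_by_position(self):
        p = _probe()
        vt = _vt([
            ("vc", "chr1", 999, 1000, "single"),    # at c_pos
            ("vg", "chr1", 1000, 1001, "single"),   # at c_pos + 1
            ("vs", "chr1", 998, 999, "single"),     # at c_pos - 1 = SBE (Type I fwd)
            ("vb", "chr1", 1019, 1020, "single"),   # probe body
        ])
        ov = {o.variant_id: o for o in overlap_probes_variants([p], vt)}
        assert ov["vc"].site_class == "C" and ov["vc"].distance_to_c == 0
        assert ov["vg"].site_class == "G" and ov["vg"].distance_to_c == 1
        assert ov["vs"].site_class == "SBE"
        assert ov["vb"].site_class == "body" and ov["vb"].distance_to_c == 20

    def test_sbe_position_is_body_on_type_ii(self):
        # c_pos - 1 is SBE only for Type I forward; on Type II it is not
        # even inside the forward-probe footprint
        p1 = _probe("a", design=Design.TYPE_I)
        p2 = _probe("b", design=Design.TYPE_II)
        vt = _vt([("v", "chr1", 998, 999, "single")])
        ov = overlap_probes_variants([p1, p2], vt)
        assert {(o.probe_id, o.site_class) for o in ov} == {("a", "SBE")}

    def test_spanning_variant_takes_precedence_class(self):
        # an indel covering C, G, SBE and body is classified as C
        p = _probe()
        vt = _vt([("indel", "chr1", 995, 1005, "indel")])
        (o,) = overlap_probes_variants([p], vt)
        assert o.site_class == "C" and o.distance_to_c == 0

    def test_genotype_matrix_positions(self):
        p = _probe()
        gm = GenotypeMatrix(
            dosage=pd.DataFrame([[0.0]], index=["rs1"], columns=["S1"]),
            chrom=pd.Series(["chr1"], index=["rs1"]),
            pos=pd.Series([1000], index=["rs1"]),
        )
        (o,) = overlap_probes_variants([p], gm)
        assert o.site_class == "C"

    def test_chromosome_mismatch(self):
        p = _probe()
        vt = _vt([("v", "1", 999, 1000, "single")])  # bare "1" vs "chr1"
        with pytest.raises(ValidationError, match="chromosome"):
            overlap_probes_variants([p], vt)

    def test_probe_shuffle_invariance(self):
        probes = [_probe(f"p{i}", c_pos=1000 + 200 * i) for i in range(5)]
        vt = _vt([(f"v{i}", "chr1", 1000 + 100 * i, 1001 + 100 * i, "single")
                  for i in range(10)])
        a = {(o.probe_id, o.variant_id, o.site_class)
             for o in overlap_probes_variants(probes, vt)}
        b = {(o.probe_id, o.variant_id, o.site_class)
             for o in overlap_probes_variants(probes[::-1], vt)}
        assert a == b


class TestCategories:
    def test_partition_and_precedence(self):
        all_ids = [f"p{i}" for i in range(6)]
        gap = ["p3", "p4", "p5"]
        measured = [ProbeVariantOverlap(p, "v", "body", 5, "single")
                    for p in ("p1", "p4")]
        annotated = [ProbeVariantOverlap(p, "w", "body", 5, "single")
                     for p in ("p2", "p4", "p5")]
        cats = categorize_probes(all_ids, gap, measured, annotated)
        assert cats.to_dict() == {
            "p0": "nongap_no_variant",
            "p1": "nongap_measured_snp",
            "p2": "nongap_annotated_variant",
            "p3": "gap_no_variant",
            "p4": "gap_measured_snp",  # measured wins over annotated
            "p5": "gap_annotated_variant",
        }
        assert set(cats.unique()) <= set(CATEGORIES)
        assert len(cats) == len(all_ids)

    def test_unknown_gap_id(self):
        with pytest.raises(ValidationError):
            categorize_probes(["p1"], ["p9"], [], [])


class TestSignalByDistance:
    def _dataset(self, effect=True, n=300, seed=0):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(n_samples=n, seed=seed)
        probes, overlaps, meth_rows, unmeth_rows, dos_rows = [], [], [], [], []
        for i, dist in enumerate((1, 5, 25, 45)):
            pid, vid = f"p{i}", f"v{i}"
            dos = simulate_genotypes(0.4, n, rng)
            if effect:
                m, u = simulate_body_snp_intensities(dos, dist, cfg, rng)
            else:
                m, u = simulate_body_snp_intensities(np.zeros(n), dist, cfg, rng)
            probes.append(pid)
            overlaps.append(ProbeVariantOverlap(pid, vid, "body", dist, "single"))
            meth_rows.append(m)
            unmeth_rows.append(u)
            dos_rows.append(dos)
        cols = [f"S{i}" for i in range(n)]
        ints = IntensityMatrices(
            meth=pd.DataFrame(meth_rows, index=probes, columns=cols),
            unmeth=pd.DataFrame(unmeth_rows, index=probes, columns=cols),
        )
        gm = GenotypeMatrix(dosage=pd.DataFrame(
            dos_rows, index=[f"v{i}" for i in range(4)], columns=cols))
        return ints, gm, overlaps

    def test_genotype_separation_decays_with_distance(self):
        ints, gm, overlaps = self._dataset(effect=True)
        summ = genotype_signal_by_distance(ints, gm, overlaps, Design.TYPE_II)
        un = summ[summ["channel"] == "unmeth"].pivot(
            index="distance", columns="genotype", values="mean")
        sep = (un["ref_hom"] - un["alt_hom"]) / un["ref_hom"]
        # separation shrinks with distance from the C site
        assert sep.loc[1] > sep.loc[25] > sep.loc[45] >= 0

    def test_unmeth_channel_less_robust(self):
        ints, gm, overlaps = self._dataset(effect=True)
        summ = genotype_signal_by_distance(ints, gm, overlaps, Design.TYPE_II)
        piv = summ.pivot_table(index="channel", columns="genotype", values="mean")
        rel_u = 1 - piv.loc["unmeth", "alt_hom"] / piv.loc["unmeth", "ref_hom"]
        rel_m = 1 - piv.loc["meth", "alt_hom"] / piv.loc["meth", "ref_hom"]
        assert rel_u > rel_m

    def test_null_genotype_curves_coincide(self):
        ints, gm, overlaps = self._dataset(effect=True)
        # all genotypes identical (all ref-hom): only one curve exists
        gm0 = GenotypeMatrix(dosage=pd.DataFrame(
            np.zeros_like(gm.dosage.to_numpy()), index=gm.dosage.index,
            columns=gm.dosage.columns))
        summ = genotype_signal_by_distance(ints, gm0, overlaps, Design.TYPE_II)
        assert set(summ["genotype"]) == {"ref_hom"}

    def test_multi_snp_probes_excluded(self):
        ints, gm, overlaps = self._dataset(effect=True)
        overlaps = overlaps + [ProbeVariantOverlap("p0", "v1", "body", 9, "single")]
        summ = genotype_signal_by_distance(ints, gm, overlaps, Design.TYPE_II)
        assert 1 not in set(summ["distance"])  # p0 (distance 1) now excluded

    def test_empty_summary(self):
        ints, gm, _ = self._dataset(effect=True)
        summ = genotype_signal_by_distance(ints, gm, [], Design.TYPE_II)
        assert summ.empty


class TestProbeSd:
    def test_known_values(self):
        data = pd.DataFrame(
            [[0.4, 0.4, 0.4], [0.0, 1.0, np.nan], [np.nan, np.nan, np.nan]],
            index=["flat", "pair", "empty"], columns=["a", "b", "c"],
        )
        sd = probe_sd(BetaMatrix(data))
        assert sd["flat"] == pytest.approx(0.0, abs=1e-12)
        assert sd["pair"] == pytest.approx(np.sqrt(0.5))  # 0.7071, n-1 denom
        assert np.isnan(sd["empty"])


class TestVariabilityEnrichment:
    def test_zero_cutoff_is_base_rate(self):
        sd = pd.Series(np.linspace(0.01, 1.0, 100), index=[f"p{i}" for i in range(100)])
        gap = [f"p{i}" for i in range(80, 100)]
        tab = variability_enrichment(sd, gap, [0])
        assert tab.loc[0, "retained"] == 100
        assert tab.loc[0, "gap_fraction"] == pytest.approx(0.2)

    def test_monotone_on_sd_ordered_fixture(self):
        # gap probes strictly more variable than every non-gap probe
        sd = pd.Series(np.concatenate([np.linspace(0.01, 0.1, 80),
                                       np.linspace(0.5, 0.9, 20)]),
                       index=[f"p{i}" for i in range(100)])
        gap = [f"p{i}" for i in range(80, 100)]
        tab = variability_enrichment(sd, gap)
        frac = tab["gap_fraction"].to_numpy()
        assert (np.diff(frac) >= -1e-12).all()
        assert frac[-1] == 1.0

    def test_percentile_99_of_100(self):
        sd = pd.Series(np.arange(1, 101, dtype=float),
                       index=[f"p{i}" for i in range(100)])
        tab = variability_enrichment(sd, [], [99])
        assert tab.loc[0, "retained"] == 1

    def test_invalid_cutoff(self):
        with pytest.raises(ValidationError):
            variability_enrichment(pd.Series([1.0]), [], [100])
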