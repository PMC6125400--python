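"""Strand-aware region classification and peak-gene association."""

import pytest

from markconcord import reference
from markconcord.annotation import (
    associate_peaks_to_genes,
    classify_region,
    signed_tss_distance,
    summarize_annotation,
    PeakGeneAssociation,
)
from markconcord.io_formats import GeneModel

from .oracles import brute_classify


PLUS = GeneModel("GP", "chr1", 10_000, 20_000, "+")     # TSS 10,000
MINUS = GeneModel("GM", "chr1", 1_000, 5_000, "-")      # TSS base 4,999


class TestClassifyRegion:
    def test_peak_covering_tss_is_tss(self):
        assert classify_region(("chr1", 9_950, 10_050), PLUS) == "tss"

    def test_peak_within_100bp_of_tss_is_tss(self):
        assert classify_region(("chr1", 10_050, 10_100), PLUS) == "tss"
        assert classify_region(("chr1", 9_850, 9_900), PLUS) == "promoter"  # 101 bp away
        assert classify_region(("chr1", 9_860, 9_901), PLUS) == "tss"  # 100 bp away

    def test_promoter_window_upstream_of_plus_gene(self):
        assert classify_region(("chr1", 8_200, 9_500), PLUS) == "promoter"

    def test_gene_body(self):
        assert classify_region(("chr1", 15_000, 15_500), PLUS) == "gene_body"

    def test_intergenic(self):
        assert classify_region(("chr1", 40_000, 41_000), PLUS) == "intergenic"

    def test_minus_strand_upstream_is_rightward(self):
        assert classify_region(("chr1", 5_600, 6_900), MINUS) == "promoter"
        assert classify_region(("chr1", 200, 900), MINUS) == "intergenic"

    def test_minus_strand_agrees_with_reflected_plus_rule(self):
        # reflect coordinates around L and flip the strand: classes must match
        L = 100_000
        for start, width in [(0, 800), (2_500, 400), (4_700, 600), (5_100, 2_000),
                             (6_950, 100), (800, 150), (4_880, 240)]:
            peak = ("chr1", start, start + width)
            refl_gene = GeneModel("R", "chr1", L - MINUS.end, L - MINUS.start, "+")
            refl_peak = ("chr1", L - peak[2], L - peak[1])
            assert classify_region(peak, MINUS) == classify_region(refl_peak, refl_gene)

    def test_chromosome_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            classify_region(("chr2", 0, 10), PLUS)

    def test_precedence_is_total(self, rnd):
        for _ in range(200):
            start = rnd.randrange(0, 30_000)
            peak = ("chr1", start, start + rnd.randrange(1, 3_000))
            assert classify_region(peak, PLUS) in (
                "tss", "promoter", "gene_body", "intergenic"
            )


class TestTssDistance:
    def test_zero_when_covering_tss(self):
        assert signed_tss_distance(("chr1", 9_990, 10_010), PLUS) == 0

    def test_negative_upstream_in_gene_orientation(self):
        assert signed_tss_distance(("chr1", 9_000, 9_500), PLUS) == -501
        # for the minus gene, genomic-right is upstream
        assert signed_tss_distance(("chr1", 5_600, 6_900), MINUS) == -601

    def test_positive_downstream(self):
        assert signed_tss_distance(("chr1", 10_200, 10_300), PLUS) == 200
        assert signed_tss_distance(("chr1", 200, 900), MINUS) == 4100


class TestAssociate:
    def test_peak_inside_one_gene_only(self, small_genes):
        (a,) = associate_peaks_to_genes([("chr1", 14_000, 14_500)], small_genes)
        assert a.gene_id == "GA" and a.region_class == "gene_body"

    def test_peak_spanning_two_promoters_gets_two_associations(self):
        genes = [
            GeneModel("L", "chr1", 8_000, 9_800, "-"),   # promoter [9600, 11800)
            GeneModel("R", "chr1", 12_000, 15_000, "+"), # promoter [10000, 12200)
        ]
        assocs = associate_peaks_to_genes([("chr1", 10_500, 11_500)], genes)
        assert {a.gene_id for a in assocs} == {"L", "R"}

    def test_max_multi_caps_associations_nearest_first(self):
        genes = [
            GeneModel(f"G{i}", "chr1", 10_000 + 300 * i, 10_200 + 300 * i, "+")
            for i in range(5)
        ]
        assocs = associate_peaks_to_genes([("chr1", 9_000, 12_000)], genes, max_multi=3)
        assert len(assocs) == 3
        dists = [abs(a.distance_bp) for a in assocs]
        assert dists == sorted(dists)

    def test_orphan_peak_assigned_to_nearest_gene_as_intergenic(self, small_genes):
        (a,) = associate_peaks_to_genes([("chr1", 60_000, 60_500)], small_genes)
        assert a.region_class == "intergenic" and a.gene_id == "GB"

    def test_empty_annotation_is_an_error(self):
        with pytest.raises(ValueError):
            associate_peaks_to_genes([("chr1", 0, 10)], [])

    def test_matches_all_pairs_bruteforce(self, rnd, small_genes):
        chr1_genes = [g for g in small_genes if g.chrom == "chr1"]
        peaks = []
        for _ in range(300):
            start = rnd.randrange(0, 100_000)
            peaks.append(("chr1", start, start + rnd.randrange(50, 4_000)))
        assocs = associate_peaks_to_genes(peaks, chr1_genes, max_multi=10)
        by_peak = {}
        for a in assocs:
            by_peak.setdefault(a.interval, []).append(a)
        for peak in peaks:
            oracle = {
                g.gene_id: brute_classify(peak, g)
                for g in chr1_genes
            }
            genic = {g: c for g, c in oracle.items() if c != "intergenic"}
            got = {a.gene_id: a.region_class for a in by_peak[peak]}
            if genic:
                assert got == genic
            else:
                # single nearest gene, intergenic
                (gid,) = got
                assert got[gid] == "intergenic"
                best = min(
                    chr1_genes,
                    key=lambda g: (abs(signed_tss_distance(peak, g)), g.start, g.gene_id),
                )
                assert gid == best.gene_id


class TestSummarize:
    def test_reported_tss_and_promoter_counts_sum_to_92(self):
        assocs = [
            PeakGeneAssociation("chr1", i, i + 1, f"g{i}", "tss", 0)
            for i in range(reference.K4_TSS_PEAKS)
        ] + [
            PeakGeneAssociation("chr1", 1000 + i, 1001 + i, f"h{i}", "promoter", -500)
            for i in range(reference.K4_PROMOTER_PEAKS)
        ]
        summary = summarize_annotation(assocs)
        assert summary["tss"] == 33 and summary["promoter"] == 59
        assert summary["tss_proximal"] == 92

    def test_empty_associations_all_zero(self):
        s = summarize_annotation([])
        assert s["tss_proximal"] == 0 and s["n_multi_gene_peaks"] == 0

    def test_multi_counts(self):
        assocs = [
            PeakGeneAssociation("chr1", 0, 10, "A", "gene_body", 5),
            PeakGeneAssociation("chr1", 0, 10, "B", "promoter", -100),
            PeakGeneAssociation("chr1", 50, 60, "A", "gene_body", 40),
        ]
        s = summarize_annotation(assocs)
        assert s["n_multi_gene_peaks"] == 1  # peak [0,10) -> A and B
        assert s["n_multi_peak_genes"] == 1  # gene A <- two peaks
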