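import math

import numpy as np
import pytest
from scipy import stats

from chipwin.annotate import (
    assign_genes,
    chromosome_enrichment,
    feature_distribution,
    tss_distance_histogram,
)
from chipwin.genome import GeneModel, GenomeBuild
from chipwin.peaks import Peak, PeakSet

GENOME = GenomeBuild((("chrA", 100_000), ("chrB", 100_000)))


def _peak(chrom, start, end, summit=None):
    return Peak(chrom=chrom, start=start, end=end, n_windows=(end - start) // 100,
                min_p=1e-6, summit=summit if summit is not None else (start + end) // 2,
                max_chip_count=10)


def _peakset(peaks):
    return PeakSet(peaks=peaks, alpha=1e-3, min_run=2)


def _gene(gid, chrom, strand, tss, length=5000):
    if strand == "+":
        tx_start, tx_end = tss, tss + length
    else:
        tx_start, tx_end = tss + 1 - length, tss + 1
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                     tx_start=tx_start, tx_end=tx_end,
                     exons=((tx_start, tx_end),))


class TestAssignGenes:
    def test_gap_at_radius_boundary_is_bound(self):
        # peak [4900, 5100) and a TSS at 10000: gap = 10000 - 5100 = 4900
        (b,) = assign_genes(_peakset([_peak("chrA", 4900, 5100)]),
                            [_gene("g", "chrA", "+", 10000)])
        assert b.bound and b.distance_to_tss == -4900

    def test_tss_inside_peak_distance_zero(self):
        (b,) = assign_genes(_peakset([_peak("chrA", 9000, 11000)]),
                            [_gene("g", "chrA", "+", 10000)])
        assert b.bound and b.distance_to_tss == 0

    def test_gap_just_beyond_radius_not_bound(self):
        (b,) = assign_genes(_peakset([_peak("chrA", 4899 - 100, 4999)]),
                            [_gene("g", "chrA", "+", 10000)])
        assert b.distance_to_tss == -5001 and not b.bound

    def test_minus_strand_sign_flips(self):
        # peak genomically right of a minus-strand TSS is upstream
        (b,) = assign_genes(_peakset([_peak("chrA", 12000, 12200)]),
                            [_gene("g", "chrA", "-", 10000)])
        assert b.distance_to_tss == -2000

    def test_infinite_radius_binds_every_gene_on_peak_chromosome(self):
        genes = [_gene(f"g{i}", "chrA", "+", 10000 + 7000 * i) for i in range(5)]
        genes.append(_gene("far", "chrB", "+", 50000))
        bindings = assign_genes(_peakset([_peak("chrA", 0, 200)]), genes,
                                tss_radius=math.inf)
        assert [b.bound for b in bindings] == [True] * 5 + [False]
        assert bindings[-1].closest_peak is None


class TestTssDistanceHistogram:
    def test_summits_at_tss_fill_central_bin(self):
        genes = [_gene("g1", "chrA", "+", 10000), _gene("g2", "chrA", "+", 50000)]
        peaks = _peakset([_peak("chrA", 9900, 10100, summit=10000),
                          _peak("chrA", 49900, 50100, summit=50000)])
        h = tss_distance_histogram(peaks, genes, max_dist=10000, bin=1000)
        central = np.flatnonzero(h.counts)
        assert list(central) == [10] and h.counts[10] == 2  # bin [0, 1000)
        assert h.frac_within_2kb == 1.0 and h.overflow == 0

    def test_no_genes_pools_everything_in_overflow(self):
        h = tss_distance_histogram(_peakset([_peak("chrA", 0, 200)]), [],
                                   max_dist=10000, bin=1000)
        assert h.overflow == 1 and h.counts.sum() == 0

    def test_minus_strand_upstream_summit_lands_in_negative_bin(self):
        # 1500 bp upstream of a minus-strand TSS = genomically tss + 1500
        gene = _gene("g", "chrA", "-", 10000)
        peaks = _peakset([_peak("chrA", 11400, 11600, summit=11500)])
        h = tss_distance_histogram(peaks, [gene], max_dist=10000, bin=1000)
        assert h.counts[np.flatnonzero(h.counts)[0]] == 1
        assert h.bin_edges[np.flatnonzero(h.counts)[0]] == -2000

    def test_total_equals_peak_count(self):
        genes = [_gene("g", "chrA", "+", 10000)]
        peaks = _peakset([_peak("chrA", 9000, 9200), _peak("chrA", 90000, 90200),
                          _peak("chrB", 0, 200)])
        h = tss_distance_histogram(peaks, genes, max_dist=5000, bin=1000)
        assert h.counts.sum() + h.overflow == h.n_peaks == 3


class TestFeatureDistribution:
    def test_all_summits_in_promoters(self):
        genes = [_gene("g1", "chrA", "+", 10000), _gene("g2", "chrA", "+", 50000)]
        peaks = _peakset([_peak("chrA", 8000, 8400, summit=8200),
                          _peak("chrA", 48000, 48400, summit=48200)])
        fd = feature_distribution(peaks, genes, GENOME)
        assert fd.fractions["promoter"] == 1.0

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError, match="no peaks"):
            feature_distribution(_peakset([]), [], GENOME)

    def test_gene_free_genome_all_intergenic(self):
        fd = feature_distribution(500, [], GENOME, seed=7)
        assert fd.fractions["intergenic"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        genes = [_gene(f"g{i}", "chrA", "+-"[i % 2], 10000 + 8000 * i)
                 for i in range(10)]
        peaks = _peakset([
            _peak("chrA", int(s), int(s) + 200) for s in rng.integers(0, 99_000, 40)
        ])
        fd = feature_distribution(peaks, genes, GENOME)
        assert sum(fd.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        fd2 = feature_distribution(1000, genes, GENOME, seed=3)
        assert sum(fd2.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestChromosomeEnrichment:
    def test_all_peaks_on_one_of_two_equal_chroms(self):
        peaks = _peakset([_peak("chrA", 1000 * i, 1000 * i + 200) for i in range(100)])
        ce = chromosome_enrichment(peaks, GENOME)
        # exact binomial: P = 2 * 2^-100
        assert ce.p_value[0] == pytest.approx(2 * 2.0**-100, rel=1e-9)
        assert ce.ratio[0] == pytest.approx(2.0)
        assert ce.expected.sum() == pytest.approx(100)

    def test_single_peak_no_significance(self):
        ce = chromosome_enrichment(_peakset([_peak("chrA", 0, 200)]), GENOME)
        assert (ce.p_value >= 0.5).all()

    def test_uniform_peaks_ratio_near_one(self, rng):
        peaks = []
        for chrom in ("chrA", "chrB"):
            for s in rng.integers(0, 99_000, 50):
                peaks.append(_peak(chrom, int(s), int(s) + 200))
        ce = chromosome_enrichment(_peakset(peaks), GENOME)
        assert np.allclose(ce.ratio, 1.0) and (ce.p_value > 1e-3).all()

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError):
            chromosome_enrichment(_peakset([]), GENOME)
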