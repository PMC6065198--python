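import itertools
import math

import numpy as np
import pytest

from devstab.errors import FormatError, ParameterError
from devstab.genomic_overlap import (
    AggregationProfile,
    GeneModel,
    GenomicInterval,
    aggregation_profile,
    assign_peaks_to_genes,
    classify_peak,
    gene_overlap_test,
    gene_set_overlap_test,
    interval_randomization,
    rank_peaks_deciles,
    read_bed,
    read_bedgraph,
    read_gene_models,
    total_bp,
    write_bed,
)


def hypergeom_upper_tail_enumeration(N, K, n, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestGeneOverlapTest:
    def test_zero_overlap_has_probability_one(self):
        assert gene_overlap_test(100, 10, 10, 0).p_value == pytest.approx(1.0)

    def test_forced_identity_spot_value(self):
        # all 5 of 5 drawn from the 5 targets among 10 genes: 1/C(10,5)
        assert gene_overlap_test(10, 5, 5, 5).p_value == pytest.approx(
            1 / 252
        )

    def test_partial_overlap_spot_value(self):
        assert gene_overlap_test(6, 3, 3, 2).p_value == pytest.approx(0.5)

    def test_matches_enumeration_on_small_grid(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = hypergeom_upper_tail_enumeration(N, K, n, k)
                        assert gene_overlap_test(N, K, n, k).p_value == \
                            pytest.approx(expected, rel=1e-9), (N, K, n, k)

    def test_genome_scale_is_finite_and_small(self):
        res = gene_overlap_test(20_000, 900, 500, 100)
        assert 0 < res.p_value < 1e-20

    @pytest.mark.parametrize("args", [(10, 11, 5, 0), (10, 5, 5, 6),
                                      (10, 5, 11, 0), (-1, 0, 0, 0)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ParameterError):
            gene_overlap_test(*args)

    def test_set_wrapper_counts_within_universe(self):
        universe = [f"g{i}" for i in range(20)]
        a = {"g0", "g1", "g2", "not_in_universe"}
        b = {"g1", "g2", "g3"}
        res = gene_set_overlap_test(universe, a, b)
        assert (res.N, res.K, res.n, res.k) == (20, 3, 3, 2)


class TestIntervalRandomization:
    def test_annotation_equals_workspace(self):
        ws = [GenomicInterval("c", 0, 100)]
        res = interval_randomization(
            [GenomicInterval("c", 20, 30)], ws, ws, n_samples=200, seed=0
        )
        assert res.fold == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_enumerable_toy_expectation(self):
        """One length-10 query in [0,100) vs annotation [0,50).

        Exhaustive enumeration over the 91 integer placements gives
        expected overlap 455/91 = 5.0 bp; the sampled mean must agree
        within 3 standard errors, and the observed overlap is 10 bp.
        """
        res = interval_randomization(
            [GenomicInterval("c", 0, 10)],
            [GenomicInterval("c", 0, 50)],
            [GenomicInterval("c", 0, 100)],
            n_samples=10_000,
            seed=1,
        )
        se = res.null_sd / math.sqrt(res.n_samples)
        assert abs(res.expected_bp - 5.0) <= 3 * se
        assert res.observed_bp == 10.0
        assert res.fold == pytest.approx(2.0, rel=0.1)

    def test_depletion_direction(self):
        res = interval_randomization(
            [GenomicInterval("c", 900, 1000)],
            [GenomicInterval("c", 0, 40)],
            [GenomicInterval("c", 0, 1000)],
            n_samples=500,
            seed=2,
        )
        assert res.observed_bp == 0.0
        assert res.fold < 1.0

    def test_deterministic_per_seed(self):
        args = (
            [GenomicInterval("c", 5, 25)],
            [GenomicInterval("c", 10, 60)],
            [GenomicInterval("c", 0, 200)],
        )
        r1 = interval_randomization(*args, n_samples=300, seed=7)
        r2 = interval_randomization(*args, n_samples=300, seed=7)
        assert r1 == r2

    def test_empty_workspace_rejected(self):
        with pytest.raises(ParameterError, match="workspace"):
            interval_randomization(
                [GenomicInterval("c", 0, 5)], [GenomicInterval("c", 0, 5)],
                [], n_samples=100, seed=0,
            )

    def test_empty_annotation_rejected(self):
        with pytest.raises(ParameterError, match="annotation"):
            interval_randomization(
                [GenomicInterval("c", 0, 5)], [],
                [GenomicInterval("c", 0, 50)], n_samples=100, seed=0,
            )

    def test_query_outside_workspace_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = interval_randomization(
                [GenomicInterval("c", 90, 120)],
                [GenomicInterval("c", 0, 100)],
                [GenomicInterval("c", 0, 100)],
                n_samples=100,
                seed=0,
            )
        assert res.observed_bp == 10.0


class TestPeakAssignment:
    GENES = [
        GeneModel("gA", "2L", 150, 300, "+"),
        GeneModel("gB", "2L", 200, 400, "-"),
        GeneModel("gC", "3R", 0, 100, "+"),
    ]

    def test_overlap_and_halfopen_touching(self):
        bound, per_peak = assign_peaks_to_genes(
            [GenomicInterval("2L", 100, 200, name="p1"),
             GenomicInterval("2L", 400, 500, name="p2")],
            self.GENES,
        )
        assert bound == {"gA"}          # p1 touches gA only; [200,300) vs
        assert per_peak == {"p1": ["gA"], "p2": []}  # end-exclusive gB span

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(12)
        peaks = [
            GenomicInterval("2L", int(s), int(s) + int(w), name=f"p{i}")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 500, 40), rng.integers(1, 60, 40))
            )
        ]
        genes = [
            GeneModel(f"g{i}", "2L", int(s), int(s) + int(w) + 1, "+")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 500, 25), rng.integers(1, 80, 25))
            )
        ]
        bound, per_peak = assign_peaks_to_genes(peaks, genes)
        expected_bound = {
            g.gene_id for g in genes for p in peaks
            if p.chrom == g.chrom and p.start < g.end and g.start < p.end
        }
        assert bound == expected_bound
        for p in peaks:
            hits = sorted(
                g.gene_id for g in genes
                if p.start < g.end and g.start < p.end
            )
            assert per_peak[p.name] == hits

    def test_input_order_invariance(self):
        b1, _ = assign_peaks_to_genes(
            [GenomicInterval("2L", 100, 200), GenomicInterval("2L", 350, 360)],
            self.GENES,
        )
        b2, _ = assign_peaks_to_genes(
            [GenomicInterval("2L", 350, 360), GenomicInterval("2L", 100, 200)],
            list(reversed(self.GENES)),
        )
        assert b1 == b2

    def test_disjoint_chromosome_names_warn(self):
        with pytest.warns(UserWarning, match="chromosome"):
            assign_peaks_to_genes(
                [GenomicInterval("chr2L", 0, 10)], self.GENES
            )


class TestDecileRanking:
    def _peaks(self, heights):
        return [
            GenomicInterval("2L", 10 * i, 10 * i + 5, height=float(h),
                            name=f"p{i}")
            for i, h in enumerate(heights)
        ]

    def test_top_decile_holds_tallest(self):
        table = rank_peaks_deciles(self._peaks(range(1, 21)))
        top = table[table["decile"] == 1]
        assert sorted(top["height"]) == [19.0, 20.0]

    def test_largest_remainder_bin_sizes(self):
        table = rank_peaks_deciles(self._peaks(range(33)))
        sizes = table.groupby("decile").size().tolist()
        assert sizes == [4, 4, 4, 3, 3, 3, 3, 3, 3, 3]

    def test_bin_sizes_never_differ_by_more_than_one(self):
        for n in (10, 17, 29, 100, 101):
            sizes = rank_peaks_deciles(
                self._peaks(np.arange(n))
            ).groupby("decile").size()
            assert sizes.max() - sizes.min() <= 1

    def test_concatenation_preserves_height_order(self):
        table = rank_peaks_deciles(self._peaks([5, 3, 8, 1, 9, 2, 7]))
        assert list(table["height"]) == sorted(table["height"], reverse=True)
        assert list(table["decile"]) == sorted(table["decile"])

    def test_equal_heights_tie_break_deterministic(self):
        t1 = rank_peaks_deciles(self._peaks([4] * 12))
        t2 = rank_peaks_deciles(list(reversed(self._peaks([4] * 12))))
        assert list(t1["name"]) == list(t2["name"])
        assert list(t1["start"]) == sorted(t1["start"])

    def test_missing_height_rejected(self):
        peaks = self._peaks([1, 2]) + [GenomicInterval("2L", 999, 1005)]
        with pytest.raises(ParameterError, match="height"):
            rank_peaks_deciles(peaks)

    def test_feature_precedence(self):
        genes = [
            GeneModel("plus", "2L", 1000, 3000, "+"),    # TSS at 1000
            GeneModel("minus", "2L", 5000, 7000, "-"),   # TSS at 6999
        ]
        # overlaps the body of `plus` AND the TSS window of nothing
        assert classify_peak(
            GenomicInterval("2L", 2000, 2100), genes, tss_window=500
        ) == "gene_body"
        # overlaps plus's TSS window and minus's body: TSS wins
        assert classify_peak(
            GenomicInterval("2L", 900, 1100), genes, tss_window=500
        ) == "TSS"
        assert classify_peak(
            GenomicInterval("2L", 6400, 6600), genes, tss_window=500
        ) == "TSS"  # minus-strand TSS at end-1
        assert classify_peak(
            GenomicInterval("2L", 9000, 9100), genes, tss_window=500
        ) == "intergenic"


class TestAggregationProfile:
    def _signal(self, length=4000, chrom="2L"):
        return {chrom: np.zeros(length)}

    def test_all_uniform_genes_raise(self):
        signal = self._signal()
        signal["2L"][:] = 3.0
        genes = [GeneModel("g1", "2L", 100, 600, "+")]
        with pytest.raises(ParameterError, match="no gene"):
            aggregation_profile(signal, genes, flank_bp=50, n_body_bins=10)

    def test_uniform_genes_listed_as_excluded(self):
        signal = self._signal()
        signal["2L"][100:600] = 2.0            # g1 uniform over its body
        signal["2L"][1000:1500] = np.linspace(0, 5, 500)
        genes = [GeneModel("g1", "2L", 100, 600, "+"),
                 GeneModel("g2", "2L", 1000, 1500, "+")]
        prof = aggregation_profile(signal, genes, flank_bp=50, n_body_bins=10)
        assert prof.excluded_genes == ["g1"]
        assert prof.n_genes == 1

    def test_tss_spike_peaks_in_first_body_bin(self):
        signal = self._signal()
        signal["2L"][1000:1010] = 50.0
        genes = [GeneModel("g", "2L", 1000, 2000, "+")]
        prof = aggregation_profile(signal, genes, flank_bp=100,
                                   n_body_bins=20, n_flank_bins=5)
        body = prof.mean[prof.n_flank_bins:
                         prof.n_flank_bins + prof.n_body_bins]
        assert np.argmax(body) == 0

    def test_linear_signals_match_hand_rescaling(self):
        """Two genes with linear ramps: bin means equal chunk averages."""
        signal = self._signal()
        signal["2L"][0:400] = np.arange(400, dtype=float)      # slope 1
        signal["2L"][1000:1200] = 2 * np.arange(200, dtype=float)
        genes = [GeneModel("gA", "2L", 0, 400, "+"),
                 GeneModel("gB", "2L", 1000, 1200, "+")]
        prof = aggregation_profile(signal, genes, flank_bp=0, n_body_bins=4)
        gA_bins = [np.mean(np.arange(400)[i * 100:(i + 1) * 100])
                   for i in range(4)]
        gB_bins = [np.mean(2 * np.arange(200)[i * 50:(i + 1) * 50])
                   for i in range(4)]
        np.testing.assert_allclose(
            prof.mean, np.mean([gA_bins, gB_bins], axis=0)
        )

    def test_minus_strand_equals_reversed_plus_profile(self):
        rng = np.random.default_rng(5)
        track = rng.random(3000)
        signal = {"2L": track}
        plus = aggregation_profile(
            signal, [GeneModel("g", "2L", 500, 1500, "+")],
            flank_bp=100, n_body_bins=10, n_flank_bins=2,
        )
        minus = aggregation_profile(
            signal, [GeneModel("g", "2L", 500, 1500, "-")],
            flank_bp=100, n_body_bins=10, n_flank_bins=2,
        )
        np.testing.assert_allclose(minus.mean, plus.mean[::-1], rtol=1e-12)

    def test_short_genes_skipped_with_warning(self):
        signal = self._signal()
        signal["2L"][:50] = np.arange(50)
        signal["2L"][100:600] = np.arange(500)
        genes = [GeneModel("tiny", "2L", 0, 5, "+"),
                 GeneModel("ok", "2L", 100, 600, "+")]
        with pytest.warns(UserWarning, match="shorter"):
            prof = aggregation_profile(signal, genes, flank_bp=0,
                                       n_body_bins=10)
        assert prof.n_genes == 1


class TestIntervalIO:
    def test_bed_roundtrip(self, tmp_path):
        peaks = [GenomicInterval("2L", 5, 50, height=7.5, name="p1"),
                 GenomicInterval("3R", 0, 10, height=1.0, name="p2")]
        path = tmp_path / "peaks.bed"
        write_bed(peaks, path)
        again = read_bed(path)
        assert again == sorted(peaks, key=lambda p: (p.chrom, p.start))

    def test_bed_rejects_bad_coordinates(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("2L\t50\t50\n")
        with pytest.raises(FormatError, match="bad.bed:1"):
            read_bed(path)

    def test_gene_tsv_and_gff_agree(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        tsv.write_text(
            "gene_id\tchrom\tstart\tend\tstrand\n"
            "gA\t2L\t99\t200\t+\n"
            "gB\t2L\t299\t400\t-\n"
        )
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "2L\tsrc\tgene\t100\t200\t.\t+\t.\tID=gA\n"
            "2L\tsrc\tgene\t300\t400\t.\t-\t.\tID=gB\n"
            "2L\tsrc\texon\t300\t350\t.\t-\t.\tID=gB.e1\n"
        )
        from_tsv = read_gene_models(tsv)
        from_gff = read_gene_models(gff)
        assert from_tsv == from_gff  # GFF 1-based closed -> half-open

    def test_bedgraph_reader(self, tmp_path):
        path = tmp_path / "sig.bedGraph"
        path.write_text("2L\t0\t10\t2.0\n2L\t10\t20\t4.0\n3R\t5\t8\t1.0\n")
        signal = read_bedgraph(path)
        assert signal["2L"][0] == 2.0 and signal["2L"][15] == 4.0
        assert signal["3R"].size == 8
        assert total_bp([GenomicInterval("2L", 0, 20)]) == 20
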