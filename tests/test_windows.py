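import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirseeds import (
    ConservationTrack,
    GeneRecord,
    GenomeAssembly,
    IntervalMask,
    define_utr,
    enumerate_windows,
    revcomp,
    window_seed,
)

SEVEN_MERS = st.text(alphabet="ACGT", min_size=7, max_size=7)


class TestDefineUtr:
    def test_plus_strand_downstream(self, flat_genome, plus_gene):
        utr = define_utr(plus_gene, flat_genome)
        assert (utr.start, utr.end) == (500, 580)
        assert utr.utr_sequence == flat_genome.chromosomes["chr1"][500:580]

    def test_minus_strand_upstream_revcomp(self, flat_genome):
        gene = GeneRecord("gB", "chr1", 300, 700, "-")
        utr = define_utr(gene, flat_genome)
        assert (utr.start, utr.end) == (220, 300)
        assert utr.utr_sequence == revcomp(
            flat_genome.chromosomes["chr1"][220:300])

    def test_clipped_at_chromosome_end(self, flat_genome):
        gene = GeneRecord("gC", "chr1", 800, 960, "+")
        utr = define_utr(gene, flat_genome)
        assert (utr.start, utr.end) == (960, 1000)
        assert len(utr) == 40

    def test_gene_abutting_edge_gives_empty_utr(self, flat_genome):
        gene = GeneRecord("gD", "chr1", 900, 1000, "+")
        utr = define_utr(gene, flat_genome)
        assert len(utr) == 0


class TestEnumerateWindows:
    def test_clean_80nt_utr_yields_74_windows(self, flat_genome, full_track,
                                              plus_gene):
        utr = define_utr(plus_gene, flat_genome)
        windows, log = enumerate_windows(utr, full_track, "spX")
        assert len(windows) == 74
        assert log.n_kept == 74 and log.n_enumerated == 74

    @pytest.mark.parametrize("gene_end,expected",
                             [(995, 0), (993, 1), (960, 34), (920, 74)])
    def test_short_utr_window_count(self, flat_genome, full_track,
                                    gene_end, expected):
        # L-6 windows for any clean UTR of length L >= 7, else none
        gene = GeneRecord("gE", "chr1", 100, gene_end, "+")
        utr = define_utr(gene, flat_genome)
        windows, _ = enumerate_windows(utr, full_track, "spX")
        assert len(windows) == expected

    def test_wcs_is_mean_of_seven_scores(self, flat_genome, plus_gene):
        arr = np.full(1000, 0.0)
        arr[500:507] = [0, 0, 0, 0, 0, 0, 0.7]
        track = ConservationTrack({"chr1": arr})
        utr = define_utr(plus_gene, flat_genome)
        windows, _ = enumerate_windows(utr, track, "spX")
        assert windows[0].wcs == pytest.approx(0.1)

    def test_constant_scores_give_constant_wcs(self, flat_genome, full_track,
                                               plus_gene):
        utr = define_utr(plus_gene, flat_genome)
        windows, _ = enumerate_windows(utr, full_track, "spX")
        assert all(w.wcs == 0.5 for w in windows)

    def test_windows_contained_in_utr_and_same_strand(self, flat_genome,
                                                      full_track):
        gene = GeneRecord("gB", "chr1", 300, 700, "-")
        utr = define_utr(gene, flat_genome)
        windows, _ = enumerate_windows(utr, full_track, "spX")
        assert len(windows) == 74
        for w in windows:
            assert utr.start <= w.start < w.end <= utr.end
            assert w.strand == "-"

    def test_minus_strand_sites_are_sense_sequence(self, full_track):
        genome = GenomeAssembly("spX", {"chr1": "A" * 100 + "GATTACA" + "C" * 93})
        gene = GeneRecord("gM", "chr1", 107, 150, "-")
        utr = define_utr(gene, genome)  # genomic [27,107)
        windows, _ = enumerate_windows(utr, full_track, "spX")
        # first window sits at the 3' end of the gene, genomic [100,107)
        assert windows[0].start == 100
        assert windows[0].site_7mer == revcomp("GATTACA")

    def test_n_base_windows_dropped(self, full_track):
        genome = GenomeAssembly("spX", {"chr1": "A" * 510 + "N" + "A" * 489})
        gene = GeneRecord("gN", "chr1", 100, 500, "+")
        utr = define_utr(gene, genome)
        windows, log = enumerate_windows(utr, full_track, "spX")
        assert log.n_n_base_dropped == 7
        assert len(windows) == 74 - 7

    def test_missing_score_windows_dropped(self, flat_genome, plus_gene):
        arr = np.full(1000, 0.5)
        arr[520] = np.nan
        track = ConservationTrack({"chr1": arr})
        utr = define_utr(plus_gene, flat_genome)
        windows, log = enumerate_windows(utr, track, "spX")
        assert log.n_missing_score_dropped == 7
        assert all(not (w.start <= 520 < w.end) for w in windows)

    def test_repeat_overlap_by_one_base_drops_window(self, flat_genome,
                                                     full_track, plus_gene):
        mask = IntervalMask("repeat", {"chr1": [(506, 510)]})
        utr = define_utr(plus_gene, flat_genome)
        windows, log = enumerate_windows(utr, full_track, "spX", mask)
        # windows starting 500..509 all touch [506,510)
        assert log.n_repeat_dropped == 10
        assert all(w.start >= 510 for w in windows)

    def test_wcs_strand_invariant(self, flat_genome, plus_gene):
        rng = np.random.default_rng(5)
        track = ConservationTrack({"chr1": rng.random(1000)})
        plus = define_utr(plus_gene, flat_genome)
        minus_gene = GeneRecord("gR", "chr1", 580, 800, "-")
        minus = define_utr(minus_gene, flat_genome)  # same interval [500,580)
        w_plus, _ = enumerate_windows(plus, track, "spX")
        w_minus, _ = enumerate_windows(minus, track, "spX")
        assert {w.start: w.wcs for w in w_plus} == \
            {w.start: w.wcs for w in w_minus}


class TestWindowSeed:
    @pytest.mark.parametrize("site,seed", [
        ("AAAAAAA", "TTTTTTT"),
        ("ACGTACG", "CGTACGT"),
    ])
    def test_default_reports_reverse_complement(self, site, seed):
        assert window_seed(site) == seed

    def test_identity_mode(self):
        assert window_seed("ACGTACG", orientation="identity") == "ACGTACG"

    @settings(derandomize=True)
    @given(SEVEN_MERS)
    def test_revcomp_is_an_involution(self, kmer):
        assert revcomp(revcomp(kmer)) == kmer

    @settings(derandomize=True)
    @given(SEVEN_MERS)
    def test_seed_site_mapping_is_a_bijection(self, kmer):
        assert window_seed(window_seed(kmer)) == kmer
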