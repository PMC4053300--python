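from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirseeds import (
    ConservationTrack,
    DiscoveryConfig,
    GeneRecord,
    GenomeAssembly,
    SeedTally,
    SpeciesBundle,
    Window,
    binomial_seed_test,
    bonferroni_call,
    run_seed_discovery,
    species_percentiles,
    tally_seeds,
)


def binom_upper_tail_bruteforce(high: int, low: int) -> Fraction:
    """Independent oracle: exact sum of Binomial(high+low, 1/2) pmf from
    ``high`` to the top of the support."""
    n = high + low
    return Fraction(sum(comb(n, j) for j in range(high, n + 1)), 2 ** n)


def make_window(site, wcs, species="sp1", gene="g1"):
    return Window(gene, species, "chr1", 0, 7, "+", site, wcs)


class TestSpeciesPercentiles:
    @pytest.mark.parametrize("values,cs50", [
        ([0.2, 0.4, 0.6, 0.8], 0.5),
        ([0.1, 0.5, 0.9], 0.5),
    ])
    def test_median_interpolation(self, values, cs50):
        s = species_percentiles("sp1", values)
        assert s.cs50 == pytest.approx(cs50)

    def test_constant_list(self):
        s = species_percentiles("sp1", [0.3] * 10)
        assert s.cs50 == s.cs95 == 0.3

    def test_ordering_invariant(self):
        rng = np.random.default_rng(3)
        s = species_percentiles("sp1", rng.random(101))
        assert 0 <= s.cs50 <= s.cs95 <= 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            species_percentiles("sp1", [])


class TestTally:
    def test_threshold_comparison(self):
        windows = {
            "a": [make_window("ACGTACG", 0.9, "a"),
                  make_window("ACGTACG", 0.9, "a")],
            "b": [make_window("ACGTACG", 0.1, "b")],
        }
        summaries = {s: species_percentiles(s, [0.5, 0.5]) for s in "ab"}
        tally = tally_seeds(windows, summaries)["ACGTACG"]
        assert (tally.count_high, tally.count_low) == (2, 1)

    def test_exact_tie_excluded_from_both_counts(self):
        windows = {"a": [make_window("ACGTACG", 0.5, "a")]}
        summaries = {"a": species_percentiles("a", [0.5, 0.5])}
        tally = tally_seeds(windows, summaries)["ACGTACG"]
        assert (tally.count_high, tally.count_low, tally.ties_excluded) == (0, 0, 1)

    def test_unobserved_7mer_absent(self):
        tallies = tally_seeds({"a": [make_window("ACGTACG", 0.9, "a")]},
                              {"a": species_percentiles("a", [0.1, 0.2])})
        assert "TTTTTTT" not in tallies

    def test_counts_partition_retained_windows(self):
        rng = np.random.default_rng(7)
        wcs = rng.choice([0.1, 0.5, 0.9], size=50)
        windows = {"a": [make_window("ACGTACG", w, "a") for w in wcs]}
        summaries = {"a": species_percentiles("a", [0.0, 1.0])}  # cs50=0.5
        t = tally_seeds(windows, summaries)["ACGTACG"]
        assert t.count_high + t.count_low + t.ties_excluded == 50

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            tally_seeds({"zz": [make_window("ACGTACG", 0.9, "zz")]}, {})


class TestBinomialTest:
    @pytest.mark.parametrize("high,low,expected", [
        (10, 0, 0.5 ** 10),
        (5, 5, 0.623046875),
        (0, 10, 1.0),
    ])
    def test_known_values(self, high, low, expected):
        call = binomial_seed_test(SeedTally("ACGTACG", high, low))
        assert call.p_raw == pytest.approx(expected, rel=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            binomial_seed_test(SeedTally("ACGTACG", 0, 0, ties_excluded=4))

    def test_seed_orientation_controls_reporting(self):
        tally = SeedTally("ACGTACG", 3, 1)
        assert binomial_seed_test(tally).seed_7mer == "CGTACGT"
        assert binomial_seed_test(tally, "identity").seed_7mer == "ACGTACG"

    def test_large_counts_no_overflow(self):
        # exact survival evaluation must stay finite and sane at n = 10^7
        call = binomial_seed_test(SeedTally("ACGTACG", 5_010_000, 4_990_000))
        assert 0.0 < call.p_raw < 1e-9

    @settings(derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20))
    def test_matches_bruteforce_oracle(self, high, low):
        if high + low == 0:
            return
        call = binomial_seed_test(SeedTally("ACGTACG", high, low))
        assert call.p_raw == pytest.approx(
            float(binom_upper_tail_bruteforce(high, low)), rel=1e-12)

    @settings(derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15))
    def test_swap_symmetry(self, high, low):
        # P(X >= high) + P(X >= low) = 1 + P(X = high) when low = n - high
        if high + low == 0:
            return
        n = high + low
        p_fwd = binomial_seed_test(SeedTally("ACGTACG", high, low)).p_raw
        p_rev = binomial_seed_test(SeedTally("ACGTACG", low, high)).p_raw
        pmf = comb(n, high) / 2 ** n
        assert p_fwd + p_rev == pytest.approx(1 + pmf, rel=1e-12)

    def test_monotone_in_count_high(self):
        n = 18
        p = [binomial_seed_test(SeedTally("ACGTACG", h, n - h)).p_raw
             for h in range(n + 1)]
        assert all(a >= b for a, b in zip(p, p[1:]))


class TestBonferroni:
    @staticmethod
    def _mk(p_raw, high=10, low=0):
        from mirseeds import SeedCall
        return SeedCall("CGTACGT", "ACGTACG", high, low, p_raw)

    def test_multiplication_and_candidate(self):
        (call,) = bonferroni_call([self._mk(1e-6)], m_tests=16384)
        assert call.p_bonferroni == pytest.approx(0.016384)
        assert call.is_candidate

    def test_cap_at_one(self):
        (call,) = bonferroni_call([self._mk(0.001)], m_tests=16384)
        assert call.p_bonferroni == 1.0 and not call.is_candidate

    def test_zero_p_stays_zero(self):
        (call,) = bonferroni_call([self._mk(0.0)], m_tests=16384)
        assert call.p_bonferroni == 0.0

    def test_depleted_7mer_never_candidate(self):
        (call,) = bonferroni_call([self._mk(1e-9, high=1, low=30)], m_tests=10)
        assert not call.is_candidate

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_call([], m_tests=0)


class TestRunSeedDiscovery:
    def test_all_equal_scores_yield_no_candidates(self):
        genome = GenomeAssembly("sp1", {"chr1": "ACGT" * 250})
        track = ConservationTrack({"chr1": np.full(1000, 0.42)})
        genes = [GeneRecord("g1", "chr1", 100, 500, "+"),
                 GeneRecord("g2", "chr1", 600, 900, "+")]
        bundle = SpeciesBundle("sp1", genome, genes, track)
        result = run_seed_discovery([bundle], DiscoveryConfig())
        # every WCS ties the median: every test is skipped
        assert result.candidate_seeds == set()
        assert result.calls == []

    def test_no_species_retained_is_hard_error(self):
        genome = GenomeAssembly("sp1", {"chr1": "ACGT" * 250})
        track = ConservationTrack({"chr1": np.full(1000, np.nan)})
        bundle = SpeciesBundle(
            "sp1", genome, [GeneRecord("g1", "chr1", 100, 500, "+")], track)
        with pytest.raises(RuntimeError):
            run_seed_discovery([bundle], DiscoveryConfig())

    def test_observed_mode_uses_tallied_7mer_count(self, small_sim):
        _, bundles, _ = small_sim
        result = run_seed_discovery(
            bundles, DiscoveryConfig(bonferroni_mode="observed"))
        assert len(result.calls) <= result.m_tests < 4 ** 7
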