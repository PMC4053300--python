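"""Candidate seed calling: CS50/CS95 percentiles, pooled high/low tallies
and the one-tailed binomial conservation test with Bonferroni correction.

The statistical idea: within each species, WCS values are ranked and the
median (CS50) splits windows into high- and low-conservation halves.
Because conservation scores are comparable only within the alignment that
produced them, only this relative rate is pooled across species.  Under no
selective constraint a given 7-mer's windows land above or below the
median with equal chance, so the pooled (high, low) counts follow
Binomial(high+low, 1/2); an excess of high-conservation windows flags the
7-mer's implied seed as a candidate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    SeedCall,
    SeedTally,
    SpeciesBundle,
    SpeciesSummary,
    Window,
)
from .windows import WindowLog, define_utr, enumerate_windows, window_seed

logger = logging.getLogger(__name__)

KMER_UNIVERSE_SIZE = 4 ** 7  # all 7-mers over {A,C,G,T}


@dataclass
class DiscoveryConfig:
    """Tunables of the seed-discovery stage.

    utr_length: nucleotides of defined 3'UTR downstream of each gene.
    k: window / seed length.
    seed_orientation: 'revcomp' reports the miRNA seed implied by each
        conserved site; 'identity' reports the site 7-mer itself.
    alpha: family-wise significance level after Bonferroni.
    bonferroni_mode: 'all_kmers' multiplies by 4^k (every testable 7-mer);
        'observed' multiplies by the number of tallied 7-mers, appropriate
        for small genomes where most 7-mers never occur.
    repeat_overlap_min_bases: minimum repeat overlap that drops a window.
    """

    utr_length: int = 80
    k: int = 7
    seed_orientation: str = "revcomp"
    alpha: float = 0.05
    bonferroni_mode: str = "all_kmers"
    repeat_overlap_min_bases: int = 1


@dataclass
class DiscoveryResult:
    """Everything the discovery stage produced, per-species and pooled."""

    calls: list[SeedCall]
    summaries: list[SpeciesSummary]
    windows_by_species: dict[str, list[Window]]
    window_logs: dict[str, list[WindowLog]]
    config: DiscoveryConfig
    m_tests: int

    @property
    def candidate_seeds(self) -> set[str]:
        return {c.seed_7mer for c in self.calls if c.is_candidate}

    def summary(self) -> str:
        lines = [
            f"species retained: {len(self.summaries)}",
            f"window records: {sum(s.n_windows for s in self.summaries)}",
            f"7-mer types observed: {len(self.calls)}",
            f"Bonferroni tests (m): {self.m_tests}",
            f"candidate seeds: {len(self.candidate_seeds)}",
        ]
        return "\n".join(lines)


def species_percentiles(species_id: str,
                        wcs_values: Sequence[float]) -> SpeciesSummary:
    """CS50 and CS95 of one species' retained-window WCS list.

    Percentiles use linear interpolation between closest order statistics,
    so the result is deterministic for a given list.
    """
    values = np.asarray(wcs_values, dtype=float)
    if values.size == 0:
        raise ValueError(f"{species_id}: no WCS values")
    cs50, cs95 = np.percentile(values, [50.0, 95.0])
    return SpeciesSummary(species_id, float(cs50), float(cs95), int(values.size))


def tally_seeds(windows_by_species: Mapping[str, Iterable[Window]],
                summaries: Mapping[str, SpeciesSummary]) -> dict[str, SeedTally]:
    """Pool high/low-conservation counts per site 7-mer across species.

    A window is 'high' if its WCS exceeds its own species' CS50, 'low' if
    below, and a tie (exactly equal) is excluded from both counts so the
    null stays at 1/2.  Only observed 7-mers appear in the result.
    """
    tallies: dict[str, SeedTally] = {}
    for species_id, windows in windows_by_species.items():
        if species_id not in summaries:
            raise KeyError(f"no percentile summary for species {species_id!r}")
        cs50 = summaries[species_id].cs50
        for w in windows:
            tally = tallies.get(w.site_7mer)
            if tally is None:
                tally = tallies[w.site_7mer] = SeedTally(w.site_7mer)
            if w.wcs > cs50:
                tally.count_high += 1
            elif w.wcs < cs50:
                tally.count_low += 1
            else:
                tally.ties_excluded += 1
    return tallies


def binomial_seed_test(tally: SeedTally,
                       seed_orientation: str = "revcomp") -> SeedCall:
    """One-tailed exact binomial test of excess high-conservation windows.

    p_raw = P(X >= count_high) for X ~ Binomial(high+low, 1/2), evaluated
    through the survival function (log-space internally), exact with no
    normal approximation even for counts in the millions.
    """
    n = tally.count_high + tally.count_low
    if n < 1:
        raise ValueError(f"{tally.site_7mer}: all windows tied; test undefined")
    p_raw = float(stats.binom.sf(tally.count_high - 1, n, 0.5))
    return SeedCall(
        seed_7mer=window_seed(tally.site_7mer, seed_orientation),
        site_7mer=tally.site_7mer,
        count_high=tally.count_high,
        count_low=tally.count_low,
        p_raw=min(p_raw, 1.0),
    )


def bonferroni_call(calls: Iterable[SeedCall], m_tests: int,
                    alpha: float = 0.05) -> list[SeedCall]:
    """Apply Bonferroni correction and the candidate decision in place.

    A 7-mer is a candidate iff its corrected P value is below ``alpha``
    AND high-conservation windows outnumber low ones (the test is
    one-sided for conservation above background; depleted 7-mers are
    never candidates).
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    out = []
    for call in calls:
        call.p_bonferroni = min(1.0, call.p_raw * m_tests)
        call.is_candidate = (call.p_bonferroni < alpha
                             and call.count_high > call.count_low)
        out.append(call)
    return out


def run_seed_discovery(bundles: Sequence[SpeciesBundle],
                       config: Optional[DiscoveryConfig] = None) -> DiscoveryResult:
    """Full discovery stage over a set of species bundles.

    Deterministic composition: define UTRs -> enumerate windows -> per
    species percentiles -> pooled tallies -> binomial test -> Bonferroni.
    Species whose retained-window list is empty are dropped with a
    warning (mirrors excluding genomes without conservation information).
    """
    config = config or DiscoveryConfig()
    windows_by_species: dict[str, list[Window]] = {}
    window_logs: dict[str, list[WindowLog]] = {}
    summaries: list[SpeciesSummary] = []

    for bundle in bundles:
        windows: list[Window] = []
        logs: list[WindowLog] = []
        for gene in bundle.genes:
            utr = define_utr(gene, bundle.genome, config.utr_length)
            if len(utr) == 0:
                logger.info("%s/%s: zero-length UTR, excluded",
                            bundle.species_id, gene.gene_id)
                continue
            wins, log = enumerate_windows(
                utr, bundle.conservation, bundle.species_id,
                bundle.repeat_mask, config.repeat_overlap_min_bases, config.k)
            windows.extend(wins)
            logs.append(log)
        if not windows:
            logger.warning("species %s: no retained windows, excluded",
                           bundle.species_id)
            continue
        windows_by_species[bundle.species_id] = windows
        window_logs[bundle.species_id] = logs
        summaries.append(species_percentiles(
            bundle.species_id, [w.wcs for w in windows]))

    if not summaries:
        raise RuntimeError("no species retained any windows")

    summary_map = {s.species_id: s for s in summaries}
    tallies = tally_seeds(windows_by_species, summary_map)
    calls = [binomial_seed_test(t, config.seed_orientation)
             for t in tallies.values()
             if t.count_high + t.count_low >= 1]
    if config.bonferroni_mode == "all_kmers":
        m_tests = 4 ** config.k
    elif config.bonferroni_mode == "observed":
        m_tests = max(1, len(tallies))
    else:
        raise ValueError(f"unknown bonferroni_mode {config.bonferroni_mode!r}")
    calls = bonferroni_call(calls, m_tests, config.alpha)
    calls.sort(key=lambda c: (c.p_bonferroni, c.seed_7mer))

    logger.info("discovery: %d species, %d windows, %d 7-mer types, "
                "%d candidates",
                len(summaries),
                sum(s.n_windows for s in summaries),
                len(calls),
                sum(c.is_candidate for c in calls))
    return DiscoveryResult(calls, summaries, windows_by_species, window_logs,
                           config, m_tests)
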