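"""Core data model for the seed-discovery pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` on the
forward (reference) strand.  GFF3 and wiggle inputs, which are 1-based,
are converted at the I/O boundary and never leak their convention into
these types.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_BASES = frozenset("ACGTN")
SEQ_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """One species' genome: ordered chromosome name -> uppercase sequence."""

    species_id: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if len(seq) < 1:
                raise ValueError(f"{self.species_id}/{name}: empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"{self.species_id}/{name}: invalid bases {sorted(bad)}"
                )

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval; ``strand`` is '+' or '-'."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


class ConservationTrack:
    """Per-base conservation scores in [0, 1]; missing positions are NaN.

    One float array per chromosome, aligned to the assembly: ``scores[i]``
    is the score of base ``i`` (0-based).  Missing is explicit (NaN), never
    imputed as 0 — a base without conservation information is not an
    unconserved base.
    """

    def __init__(self, scores: dict[str, np.ndarray]):
        self.scores = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            present = arr[~np.isnan(arr)]
            if present.size and (present.min() < 0 or present.max() > 1):
                raise ValueError(f"{chrom}: conservation score outside [0,1]")
            self.scores[chrom] = arr

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.scores[chrom][start:end]


@dataclass
class IntervalMask:
    """A set of masked intervals (repeats or coding regions).

    Membership is by any overlap; overlapping input intervals are allowed.
    """

    role: str  # "repeat" | "coding"
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # sort per chromosome so overlap queries can early-exit
        for chrom in self.intervals:
            self.intervals[chrom] = sorted(self.intervals[chrom])

    def add(self, chrom: str, start: int, end: int) -> None:
        self.intervals.setdefault(chrom, []).append((start, end))
        self.intervals[chrom].sort()

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Maximum number of bases of [start,end) covered by any one interval."""
        best = 0
        for s, e in self.intervals.get(chrom, []):
            if s >= end:
                break
            ov = min(e, end) - max(s, start)
            if ov > best:
                best = ov
        return best

    def overlaps(self, chrom: str, start: int, end: int, min_bases: int = 1) -> bool:
        return self.overlap_bases(chrom, start, end) >= min_bases


@dataclass
class UTRRegion:
    """The defined 3'UTR: up to ``utr_length`` nt immediately 3' of a gene.

    ``utr_sequence`` is the 5'->3' sense-strand sequence (reverse
    complemented for minus-strand genes).  Zero-length regions (gene abuts
    the chromosome edge) are legal but yield no windows.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    utr_sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Window:
    """A 7-nt sliding window with its Window Conservation Score (WCS).

    ``site_7mer`` is the sense-strand 7-mer; ``wcs`` the arithmetic mean of
    the 7 per-base conservation scores (strand-independent).
    """

    gene_id: str
    species_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    site_7mer: str
    wcs: float


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species WCS percentile thresholds over all retained windows."""

    species_id: str
    cs50: float
    cs95: float
    n_windows: int


@dataclass
class SeedTally:
    """Pooled high/low-conservation window counts for one site 7-mer.

    high: windows with WCS strictly above their species' CS50;
    low: strictly below; ties (WCS == CS50) are excluded from the test.
    """

    site_7mer: str
    count_high: int = 0
    count_low: int = 0
    ties_excluded: int = 0


@dataclass
class SeedCall:
    """Result of the one-tailed binomial test for one 7-mer."""

    seed_7mer: str
    site_7mer: str
    count_high: int
    count_low: int
    p_raw: float
    p_bonferroni: float = float("nan")
    is_candidate: bool = False


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two seed sets drawn from a universe of N."""

    N: int
    M: int
    n: int
    k: int
    p_point: float
    p_value: float


@dataclass(frozen=True)
class TargetSite:
    """A window surviving the target filters (candidate seed, WCS > CS95,
    no coding overlap)."""

    species_id: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    site_7mer: str
    seed_7mer: str
    wcs: float


@dataclass
class TargetGeneList:
    """Per-species deduplicated target genes with the annotated-gene share."""

    species_id: str
    gene_ids: set[str]
    site_counts: dict[str, int]
    n_annotated_genes: int

    @property
    def proportion(self) -> float:
        """Percentage of annotated genes with >= 1 surviving target site."""
        return 100.0 * len(self.gene_ids) / self.n_annotated_genes


@dataclass
class SpeciesBundle:
    """All inputs for one species, in pipeline coordinates."""

    species_id: str
    genome: GenomeAssembly
    genes: list[GeneRecord]
    conservation: ConservationTrack
    repeat_mask: Optional[IntervalMask] = None
    coding_mask: Optional[IntervalMask] = None
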