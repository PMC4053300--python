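"""3'UTR definition, 7-nt sliding windows and Window Conservation Scores.

Archaeal gene annotations carry no UTR coordinates, so the 3'UTR is taken
to be a fixed number of nucleotides (default 80) immediately downstream of
the annotated gene end, strand-aware and clipped at chromosome edges.
Windows slide 5'->3' along the UTR sense strand with step 1; the WCS of a
window is the arithmetic mean of its 7 genomic per-base conservation
scores, which makes it strand-independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    ConservationTrack,
    GeneRecord,
    GenomeAssembly,
    IntervalMask,
    UTRRegion,
    Window,
    revcomp,
)

DEFAULT_UTR_LENGTH = 80
WINDOW_K = 7


@dataclass
class WindowLog:
    """Per-UTR accounting of silent window exclusions."""

    gene_id: str
    n_enumerated: int = 0
    n_repeat_dropped: int = 0
    n_n_base_dropped: int = 0
    n_missing_score_dropped: int = 0
    n_kept: int = 0


def define_utr(gene: GeneRecord, genome: GenomeAssembly,
               utr_length: int = DEFAULT_UTR_LENGTH) -> UTRRegion:
    """Define the 3'UTR immediately downstream of ``gene``.

    Plus strand: ``[gene.end, gene.end + utr_length)``; minus strand:
    ``[gene.start - utr_length, gene.start)`` with the sequence reverse
    complemented so ``utr_sequence`` always reads 5'->3' on the gene's
    sense strand.  Clipped at chromosome boundaries; a gene abutting the
    edge yields a zero-length region (no windows downstream).
    """
    chrom_length = genome.length(gene.chromosome)
    if gene.strand == "+":
        start = gene.end
        end = min(gene.end + utr_length, chrom_length)
    else:
        start = max(gene.start - utr_length, 0)
        end = gene.start
    seq = genome.chromosomes[gene.chromosome][start:end]
    if gene.strand == "-":
        seq = revcomp(seq)
    return UTRRegion(gene.gene_id, gene.chromosome, start, end, gene.strand, seq)


def enumerate_windows(utr: UTRRegion, track: ConservationTrack,
                      species_id: str,
                      repeat_mask: Optional[IntervalMask] = None,
                      repeat_overlap_min_bases: int = 1,
                      k: int = WINDOW_K) -> tuple[list[Window], WindowLog]:
    """Enumerate k-nt windows at step 1 along the UTR sense strand.

    Windows are dropped (silently, tallied in the log) when they overlap a
    repeat interval by >= ``repeat_overlap_min_bases`` bases, contain an N
    base, or cover any position with a missing conservation score.  A clean
    full-length 80-nt UTR yields exactly 74 windows.
    """
    log = WindowLog(gene_id=utr.gene_id)
    L = len(utr)
    if L < k:
        return [], log
    genomic_scores = track.get(utr.chromosome, utr.start, utr.end)
    windows: list[Window] = []
    for offset in range(L - k + 1):
        log.n_enumerated += 1
        # sense-strand offset -> genomic interval
        if utr.strand == "+":
            g_start = utr.start + offset
        else:
            g_start = utr.end - offset - k
        g_end = g_start + k
        if repeat_mask is not None and repeat_mask.overlaps(
                utr.chromosome, g_start, g_end, repeat_overlap_min_bases):
            log.n_repeat_dropped += 1
            continue
        site = utr.utr_sequence[offset:offset + k]
        if "N" in site:
            log.n_n_base_dropped += 1
            continue
        scores = genomic_scores[g_start - utr.start:g_end - utr.start]
        if np.isnan(scores).any():
            log.n_missing_score_dropped += 1
            continue
        windows.append(Window(
            gene_id=utr.gene_id, species_id=species_id,
            chromosome=utr.chromosome, start=g_start, end=g_end,
            strand=utr.strand, site_7mer=site, wcs=float(scores.mean()),
        ))
    log.n_kept = len(windows)
    return windows, log


def window_seed(window_or_site, orientation: str = "revcomp") -> str:
    """Map a UTR site 7-mer to the miRNA seed it implies.

    The canonical interaction is Watson-Crick pairing of the seed with its
    site, so the default reports the reverse complement of the site;
    ``orientation='identity'`` reports the site 7-mer itself.
    """
    site = window_or_site.site_7mer if isinstance(window_or_site, Window) \
        else window_or_site
    if orientation == "revcomp":
        return revcomp(site)
    if orientation == "identity":
        return site
    raise ValueError(f"unknown seed orientation {orientation!r}")
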