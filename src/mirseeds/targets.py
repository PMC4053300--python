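"""Target-site extraction and per-species target-gene lists.

A window becomes a target site when (i) its implied seed is among the
discovery candidates, (ii) its WCS strictly exceeds its species' CS95 —
a stringent conservation gate that trades sensitivity for precision —
and (iii) it overlaps no coding interval by even one base.  Coding
overlap is excluded only here, not at seed calling: ORF-overlapped UTR
regions carry coding-selection conservation that would inflate a target
call, while at the seed-calling stage every 7-mer has the same chance of
landing in coding sequence so the relative high/low rates are unbiased.
"""
from __future__ import annotations

import logging
import os
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .types import IntervalMask, SpeciesSummary, TargetGeneList, TargetSite, Window
from .windows import window_seed

logger = logging.getLogger(__name__)


@dataclass
class TargetFilterLog:
    """How many windows each criterion dropped."""

    n_windows: int = 0
    n_not_candidate: int = 0
    n_below_cs95: int = 0
    n_coding_overlap: int = 0
    n_kept: int = 0


def call_target_sites(windows_by_species: Mapping[str, Iterable[Window]],
                      candidate_seeds: set[str],
                      summaries: Mapping[str, SpeciesSummary],
                      coding_masks: Optional[Mapping[str, IntervalMask]] = None,
                      seed_orientation: str = "revcomp",
                      ) -> tuple[list[TargetSite], TargetFilterLog]:
    """Filter windows down to high-confidence target sites.

    ``coding_masks`` maps species_id -> coding IntervalMask (a missing
    entry means no coding exclusion for that species).  Output is sorted
    by (species, chromosome, start).
    """
    log = TargetFilterLog()
    sites: list[TargetSite] = []
    for species_id, windows in windows_by_species.items():
        if species_id not in summaries:
            raise KeyError(f"no percentile summary for species {species_id!r}")
        cs95 = summaries[species_id].cs95
        mask = coding_masks.get(species_id) if coding_masks else None
        for w in windows:
            log.n_windows += 1
            seed = window_seed(w.site_7mer, seed_orientation)
            if seed not in candidate_seeds:
                log.n_not_candidate += 1
                continue
            if not w.wcs > cs95:  # strict: a tie with CS95 is dropped
                log.n_below_cs95 += 1
                continue
            if mask is not None and mask.overlaps(w.chromosome, w.start, w.end):
                log.n_coding_overlap += 1
                continue
            sites.append(TargetSite(
                species_id=species_id, gene_id=w.gene_id,
                chromosome=w.chromosome, start=w.start, end=w.end,
                strand=w.strand, site_7mer=w.site_7mer, seed_7mer=seed,
                wcs=w.wcs,
            ))
    log.n_kept = len(sites)
    sites.sort(key=lambda s: (s.species_id, s.chromosome, s.start))
    logger.info("target filtering: %d windows -> %d sites "
                "(%d non-candidate, %d below CS95, %d coding-overlap)",
                log.n_windows, log.n_kept, log.n_not_candidate,
                log.n_below_cs95, log.n_coding_overlap)
    return sites, log


def aggregate_target_genes(sites: Iterable[TargetSite],
                           annotated_gene_counts: Mapping[str, int],
                           ) -> list[TargetGeneList]:
    """Deduplicate target genes per species and compute the percentage of
    annotated genes hit.

    Every species in ``annotated_gene_counts`` appears in the output, with
    an empty gene set when no site survived there.
    """
    per_species: dict[str, Counter] = defaultdict(Counter)
    for s in sites:
        per_species[s.species_id][s.gene_id] += 1
    out = []
    for species_id in sorted(annotated_gene_counts):
        n_genes = annotated_gene_counts[species_id]
        if n_genes <= 0:
            raise ValueError(f"{species_id}: zero annotated genes")
        counts = per_species.get(species_id, Counter())
        out.append(TargetGeneList(
            species_id=species_id,
            gene_ids=set(counts),
            site_counts=dict(counts),
            n_annotated_genes=n_genes,
        ))
    unknown = set(per_species) - set(annotated_gene_counts)
    if unknown:
        raise KeyError(f"sites reference species without gene totals: {unknown}")
    return out


def export_gene_lists(lists: Iterable[TargetGeneList],
                      annotated_genes: Mapping[str, Iterable[str]],
                      out_dir: str) -> list[str]:
    """Write per-species foreground (target genes) and background (all
    annotated genes) lists — the two inputs a DAVID-style functional
    enrichment needs.  Foreground files are written even when empty.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for lst in lists:
        fg = os.path.join(out_dir, f"{lst.species_id}.targets.txt")
        bg = os.path.join(out_dir, f"{lst.species_id}.background.txt")
        background = sorted(annotated_genes[lst.species_id])
        missing = lst.gene_ids - set(background)
        if missing:
            raise ValueError(
                f"{lst.species_id}: target genes absent from annotation: "
                f"{sorted(missing)[:5]}")
        with open(fg, "w") as fh:
            for gene in sorted(lst.gene_ids):
                fh.write(gene + "\n")
        with open(bg, "w") as fh:
            for gene in background:
                fh.write(gene + "\n")
        paths.extend([fg, bg])
    return paths


def write_target_gene_summary(lists: Iterable[TargetGeneList], path: str) -> None:
    """Per-species TSV: species_id, n_target_genes, n_annotated_genes,
    proportion_pct."""
    import pandas as pd

    df = pd.DataFrame(
        [(l.species_id, len(l.gene_ids), l.n_annotated_genes,
          format(l.proportion, ".6g")) for l in lists],
        columns=["species_id", "n_target_genes", "n_annotated_genes",
                 "proportion_pct"],
    ).sort_values("species_id", kind="mergesort", ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
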