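"""End-to-end orchestration: discovery -> target annotation -> outputs.

Given a set of species bundles, runs the seed-discovery stage, filters
target sites against the per-species CS95 and coding intervals, and
writes every output table.  Identical inputs and config always produce
byte-identical files.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

from . import io as gio
from .discovery import DiscoveryConfig, DiscoveryResult, run_seed_discovery
from .targets import (
    TargetFilterLog,
    aggregate_target_genes,
    call_target_sites,
    export_gene_lists,
    write_target_gene_summary,
)
from .types import SpeciesBundle, TargetGeneList, TargetSite


@dataclass
class PipelineResult:
    discovery: DiscoveryResult
    target_sites: list[TargetSite]
    target_filter_log: TargetFilterLog
    target_gene_lists: list[TargetGeneList]

    def summary(self) -> str:
        lines = [self.discovery.summary(),
                 f"target sites: {len(self.target_sites)}",
                 f"species with target genes: "
                 f"{sum(1 for l in self.target_gene_lists if l.gene_ids)}"]
        props = [l.proportion for l in self.target_gene_lists]
        if props:
            lines.append("target-gene proportion (%): "
                         f"min {min(props):.4g}, mean "
                         f"{sum(props) / len(props):.4g}, max {max(props):.4g}")
        return "\n".join(lines)


def run_pipeline(bundles: Sequence[SpeciesBundle],
                 config: Optional[DiscoveryConfig] = None,
                 out_dir: Optional[str] = None) -> PipelineResult:
    """Run discovery and target extraction; write outputs when ``out_dir``
    is given (seed_table.tsv, species_summary.tsv, target_sites.bed,
    target_genes.tsv, gene_lists/)."""
    config = config or DiscoveryConfig()
    discovery = run_seed_discovery(bundles, config)

    summary_map = {s.species_id: s for s in discovery.summaries}
    coding_masks = {b.species_id: b.coding_mask for b in bundles
                    if b.coding_mask is not None}
    sites, flog = call_target_sites(
        discovery.windows_by_species, discovery.candidate_seeds,
        summary_map, coding_masks, config.seed_orientation)

    gene_counts = {b.species_id: len(b.genes) for b in bundles
                   if b.species_id in summary_map}
    gene_lists = aggregate_target_genes(sites, gene_counts)

    result = PipelineResult(discovery, sites, flog, gene_lists)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        gio.write_seed_table(discovery.calls,
                             os.path.join(out_dir, "seed_table.tsv"))
        gio.write_species_summaries(discovery.summaries,
                                    os.path.join(out_dir, "species_summary.tsv"))
        gio.write_target_sites(sites, os.path.join(out_dir, "target_sites.bed"))
        write_target_gene_summary(gene_lists,
                                  os.path.join(out_dir, "target_genes.tsv"))
        annotated = {b.species_id: [g.gene_id for g in b.genes]
                     for b in bundles if b.species_id in summary_map}
        export_gene_lists(gene_lists, annotated,
                          os.path.join(out_dir, "gene_lists"))
    return result
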