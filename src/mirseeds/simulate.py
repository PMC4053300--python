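"""Synthetic multi-species genome bundles with planted conserved seed sites.

The generator emulates the statistical structure the discovery pipeline
assumes: each species has a genome of uniform base composition, evenly
spaced non-overlapping genes on random strands, a per-base conservation
track whose background scores come from a low-mean Beta distribution, and
— for each chosen "true" seed — target sites (the seed's reverse
complement) written into a fraction of 3'UTRs with their 7 bases' scores
redrawn from a high-mean Beta.  Everything derives from one integer RNG
seed, so a config generates byte-identical bundles every time.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    ConservationTrack,
    GeneRecord,
    GenomeAssembly,
    IntervalMask,
    SpeciesBundle,
    revcomp,
)
from .windows import window_seed

BASES = np.array(list("ACGT"))

DEFAULT_TRUE_SEEDS = ("ACGTACG", "TTGGCCA", "GATCGAT", "CCCAAAT", "TGTGTGA")


@dataclass
class SimConfig:
    """Study conditions for one simulated bundle.

    Background scores come from Beta(mean*conc, (1-mean)*conc); planted
    site scores likewise with a high mean.  Defaults: 10 species, 200
    genes per 100 kb chromosome, 5 true seeds planted in 20% of UTRs,
    background mean 0.3, planted mean 0.95.
    """

    seed: int = 0
    n_species: int = 10
    chrom_length: int = 100_000
    n_genes: int = 200
    gene_length: int = 300
    utr_length: int = 80
    true_seeds: tuple[str, ...] = DEFAULT_TRUE_SEEDS
    plant_prob: float = 0.2
    background_mean: float = 0.3
    background_concentration: float = 8.0
    planted_mean: float = 0.95
    planted_concentration: float = 50.0
    repeat_frac: float = 0.0
    repeat_length: int = 100
    seed_orientation: str = "revcomp"
    plant_in_repeats: bool = False
    mask_flank_scores: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must be in [0,1]")
        for s in self.true_seeds:
            if len(s) != 7 or set(s) - set("ACGT"):
                raise ValueError(f"invalid true seed {s!r}")
        for m in (self.background_mean, self.planted_mean):
            if not 0.0 < m < 1.0:
                raise ValueError("score distribution means must be in (0,1)")


@dataclass(frozen=True)
class PlantedSite:
    species_id: str
    gene_id: str
    utr_offset: int
    seed_7mer: str
    chromosome: str
    start: int
    end: int


@dataclass
class GroundTruth:
    true_seeds: tuple[str, ...]
    planted_sites: list[PlantedSite] = field(default_factory=list)


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def _layout_genes(config: SimConfig, rng: np.random.Generator,
                  species_id: str) -> list[GeneRecord]:
    """Evenly slotted genes with random jitter; consecutive genes stay
    >= 2*utr_length apart so no two UTRs can overlap, and UTRs never run
    off the chromosome."""
    slot = (config.chrom_length - config.utr_length) // config.n_genes
    jitter_max = slot - config.gene_length - 2 * config.utr_length
    if jitter_max < 0:
        raise ValueError(
            f"infeasible packing: {config.n_genes} genes of "
            f"{config.gene_length} nt (+2x{config.utr_length} nt UTR "
            f"spacing) do not fit a {config.chrom_length} nt chromosome")
    genes = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        off = int(rng.integers(0, jitter_max + 1)) if jitter_max else 0
        start = config.utr_length + i * slot + off
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"{species_id}_g{i:0{width}d}", "chr1",
                                start, start + config.gene_length, strand))
    return genes


def _utr_interval(gene: GeneRecord, utr_length: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.end, gene.end + utr_length
    return gene.start - utr_length, gene.start


def _simulate_species(config: SimConfig, species_id: str,
                      rng: np.random.Generator,
                      truth: GroundTruth) -> SpeciesBundle:
    n = config.chrom_length
    seq = rng.choice(BASES, size=n)
    a, b = _beta_params(config.background_mean, config.background_concentration)
    scores = rng.beta(a, b, size=n)
    genes = _layout_genes(config, rng, species_id)

    pa, pb = _beta_params(config.planted_mean, config.planted_concentration)
    planted_intervals: list[tuple[int, int]] = []
    for gene in genes:
        utr_start, utr_end = _utr_interval(gene, config.utr_length)
        taken: list[tuple[int, int]] = []
        for true_seed in config.true_seeds:
            if rng.random() >= config.plant_prob:
                continue
            # site sequence on the UTR sense strand
            site = (revcomp(true_seed)
                    if config.seed_orientation == "revcomp" else true_seed)
            placed = None
            for _ in range(20):  # keep plantings >= 6 nt apart in the UTR
                off = int(rng.integers(0, config.utr_length - 7 + 1))
                if all(off + 7 + 6 <= s or off >= e + 6 for s, e in taken):
                    placed = off
                    break
            if placed is None:
                continue
            taken.append((placed, placed + 7))
            if gene.strand == "+":
                g_start = utr_start + placed
                genomic_site = site
            else:
                g_start = utr_end - placed - 7
                genomic_site = revcomp(site)
            seq[g_start:g_start + 7] = list(genomic_site)
            scores[g_start:g_start + 7] = rng.beta(pa, pb, size=7)
            planted_intervals.append((g_start, g_start + 7))
            truth.planted_sites.append(PlantedSite(
                species_id, gene.gene_id, placed, true_seed,
                "chr1", g_start, g_start + 7))

    if config.mask_flank_scores and planted_intervals:
        # Planted conservation bleeds into windows that overlap a site by
        # 1-6 bases, which would make the site's shifted 7-mers spuriously
        # significant.  Marking the 6 flanking bases' scores as missing
        # makes the pipeline drop those partially overlapping windows, so
        # the simulation measures seed-level recovery, not positional
        # bleed (a real-data effect the generator deliberately removes).
        is_planted = np.zeros(n, dtype=bool)
        for s, e in planted_intervals:
            is_planted[s:e] = True
        for s, e in planted_intervals:
            for pos in range(max(0, s - 6), min(n, e + 6)):
                if not is_planted[pos] and (pos < s or pos >= e):
                    scores[pos] = np.nan

    repeat_mask = _place_repeats(config, rng, planted_intervals)
    coding_mask = IntervalMask(
        role="coding",
        intervals={"chr1": [(g.start, g.end) for g in genes]})

    genome = GenomeAssembly(species_id, {"chr1": "".join(seq)})
    track = ConservationTrack({"chr1": scores})
    return SpeciesBundle(species_id, genome, genes, track,
                         repeat_mask, coding_mask)


def _place_repeats(config: SimConfig, rng: np.random.Generator,
                   planted: list[tuple[int, int]]) -> IntervalMask:
    mask = IntervalMask(role="repeat", intervals={"chr1": []})
    if config.plant_in_repeats:
        # adversarial scenario: the planted sites themselves are repeats,
        # so the repeat filter must erase the signal
        for s, e in planted:
            mask.add("chr1", s, e)
        return mask
    if config.repeat_frac <= 0:
        return mask
    target = int(config.repeat_frac * config.chrom_length)
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        start = int(rng.integers(0, config.chrom_length - config.repeat_length))
        end = start + config.repeat_length
        if any(start < pe and ps < end for ps, pe in planted):
            continue
        mask.add("chr1", start, end)
        covered += config.repeat_length
    return mask


def simulate_bundle(config: SimConfig,
                    out_dir: Optional[str] = None,
                    ) -> tuple[list[SpeciesBundle], GroundTruth]:
    """Generate a multi-species bundle; optionally write it as standard
    files (FASTA, GFF3, fixedStep wiggle, repeat BED, truth TSV).

    Returns the in-memory bundles plus ground truth; the files, when
    requested, are exactly what :mod:`mirseeds.io` reads back.
    """
    truth = GroundTruth(true_seeds=tuple(config.true_seeds))
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_species)
    bundles = []
    width = len(str(config.n_species))
    for i, ss in enumerate(child_seeds):
        species_id = f"sp{i:0{width}d}"
        rng = np.random.default_rng(ss)
        bundles.append(_simulate_species(config, species_id, rng, truth))
    if out_dir is not None:
        write_bundle_files(bundles, truth, out_dir)
    return bundles, truth


def write_bundle_files(bundles: list[SpeciesBundle], truth: GroundTruth,
                       out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for bundle in bundles:
        sp_dir = os.path.join(out_dir, bundle.species_id)
        os.makedirs(sp_dir, exist_ok=True)
        with open(os.path.join(sp_dir, "genome.fa"), "w") as fh:
            for chrom, seq in bundle.genome.chromosomes.items():
                fh.write(f">{chrom}\n")
                for j in range(0, len(seq), 70):
                    fh.write(seq[j:j + 70] + "\n")
        with open(os.path.join(sp_dir, "genes.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for g in bundle.genes:
                attrs = f"ID={g.gene_id}"
                fh.write(f"{g.chromosome}\tsim\tgene\t{g.start + 1}\t{g.end}"
                         f"\t.\t{g.strand}\t.\t{attrs}\n")
                fh.write(f"{g.chromosome}\tsim\tCDS\t{g.start + 1}\t{g.end}"
                         f"\t.\t{g.strand}\t0\tID=cds_{g.gene_id};"
                         f"Parent={g.gene_id}\n")
        with open(os.path.join(sp_dir, "conservation.wig"), "w") as fh:
            for chrom, arr in bundle.conservation.scores.items():
                # one fixedStep block per contiguous run of present scores;
                # missing positions are simply not covered
                present = ~np.isnan(arr)
                pos = 0
                while pos < arr.size:
                    if not present[pos]:
                        pos += 1
                        continue
                    run_end = pos
                    while run_end < arr.size and present[run_end]:
                        run_end += 1
                    fh.write(f"fixedStep chrom={chrom} start={pos + 1} step=1\n")
                    fh.write("\n".join(format(v, ".6f")
                                       for v in arr[pos:run_end]) + "\n")
                    pos = run_end
        with open(os.path.join(sp_dir, "repeats.bed"), "w") as fh:
            if bundle.repeat_mask is not None:
                for chrom, ivs in bundle.repeat_mask.intervals.items():
                    for s, e in ivs:
                        fh.write(f"{chrom}\t{s}\t{e}\trepeat\n")
    with open(os.path.join(out_dir, "ground_truth.tsv"), "w") as fh:
        fh.write("species_id\tgene_id\tutr_offset\tseed_7mer\tchromosome"
                 "\tstart\tend\n")
        for p in truth.planted_sites:
            fh.write(f"{p.species_id}\t{p.gene_id}\t{p.utr_offset}"
                     f"\t{p.seed_7mer}\t{p.chromosome}\t{p.start}\t{p.end}\n")


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    n_true: int
    n_recovered: int
    false_positives: tuple[str, ...]

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positives)


def evaluate_recovery(calls, truth: GroundTruth,
                      seed_orientation: str = "revcomp") -> RecoveryReport:
    """Compare called candidate seeds against the planted truth.

    ``calls`` may be a DiscoveryResult, a list of SeedCall, or a set of
    seed strings.  With the 'identity' orientation the truth seeds are
    mapped to their planted site 7-mers before comparison.
    """
    if hasattr(calls, "candidate_seeds"):
        called = set(calls.candidate_seeds)
    elif calls and hasattr(next(iter(calls)), "seed_7mer"):
        called = {c.seed_7mer for c in calls if c.is_candidate}
    else:
        called = set(calls)
    true = set(truth.true_seeds)
    if seed_orientation == "identity":
        true = {revcomp(s) for s in true}
    recovered = called & true
    return RecoveryReport(
        sensitivity=len(recovered) / len(true) if true else float("nan"),
        n_true=len(true),
        n_recovered=len(recovered),
        false_positives=tuple(sorted(called - true)),
    )
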