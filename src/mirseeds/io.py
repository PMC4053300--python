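"""Readers and writers for the standard genomic text formats.

Conventions enforced at this boundary:

* internal coordinates are 0-based half-open everywhere;
* GFF3 (1-based closed) and wiggle (1-based starts) are converted on read;
* BED and bedGraph are kept as-is (already 0-based half-open);
* soft-masked (lowercase) FASTA bases are uppercased and NOT treated as
  repeats — repeat exclusion comes only from an explicit repeat mask BED.
"""
from __future__ import annotations

import os
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

import gffutils

from .types import (
    ConservationTrack,
    GeneRecord,
    GenomeAssembly,
    IntervalMask,
    SeedCall,
    TargetSite,
)

SEED_TABLE_COLUMNS = [
    "seed_7mer",
    "site_7mer",
    "count_high",
    "count_low",
    "p_raw",
    "p_bonferroni",
    "is_candidate",
]


class FormatError(ValueError):
    """A malformed or out-of-contract input record."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str, species_id: str,
               chrom_filter: Optional[Callable[[str], bool]] = None) -> GenomeAssembly:
    """Read a (multi-record) FASTA into a :class:`GenomeAssembly`.

    ``chrom_filter`` drops sequences (e.g. plasmids / unplaced scaffolds)
    by name; the default keeps everything present in the file.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if chrom_filter is not None and not chrom_filter(rec.id):
            continue
        if rec.id in chroms:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise FormatError(f"{path}: no sequences retained")
    return GenomeAssembly(species_id=species_id, chromosomes=chroms)


def read_genes_bed(path: str, genome: GenomeAssembly) -> list[GeneRecord]:
    """Read genes from BED4/BED6 (0-based half-open, as BED defines)."""
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED fields")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            _check_gene(genome, chrom, start, end, name, seen, f"{path}:{lineno}")
            genes.append(GeneRecord(name, chrom, start, end, strand))
    return genes


def read_genes_gff3(path: str, genome: GenomeAssembly,
                    feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene features from GFF3, converting 1-based closed -> 0-based
    half-open."""
    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    seen = set()
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        start, end = feat.start - 1, feat.end
        _check_gene(genome, feat.seqid, start, end, gene_id, seen,
                    f"{path}: feature {gene_id}")
        genes.append(GeneRecord(gene_id, feat.seqid, start, end, feat.strand))
    return genes


def _check_gene(genome, chrom, start, end, gene_id, seen, where):
    if chrom not in genome.chromosomes:
        raise FormatError(f"{where}: unknown chromosome {chrom!r} for {gene_id!r}")
    if not (0 <= start < end <= genome.length(chrom)):
        raise FormatError(f"{where}: interval [{start},{end}) outside {chrom}")
    if gene_id in seen:
        raise FormatError(f"{where}: duplicate gene_id {gene_id!r}")
    seen.add(gene_id)


def read_mask_bed(path: str, role: str, genome: GenomeAssembly,
                  gff_cds: bool = False) -> IntervalMask:
    """Read an interval mask from BED, or CDS features from GFF3 when
    ``gff_cds`` is set."""
    mask = IntervalMask(role=role, intervals={})
    if gff_cds:
        db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
        for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
            _check_interval(genome, feat.seqid, feat.start - 1, feat.end, path)
            mask.add(feat.seqid, feat.start - 1, feat.end)
        return mask
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            _check_interval(genome, chrom, start, end, f"{path}:{lineno}")
            mask.add(chrom, start, end)
    return mask


def _check_interval(genome, chrom, start, end, where):
    if chrom not in genome.chromosomes:
        raise FormatError(f"{where}: unknown chromosome {chrom!r}")
    if not (0 <= start < end <= genome.length(chrom)):
        raise FormatError(f"{where}: interval [{start},{end}) outside {chrom}")


def read_conservation(path: str, genome: GenomeAssembly) -> ConservationTrack:
    """Read a conservation track from fixedStep / variableStep wiggle or
    bedGraph (auto-detected).  Uncovered positions stay missing (NaN).

    Wiggle positions are 1-based and converted; bedGraph is 0-based
    half-open already.
    """
    scores = {chrom: np.full(genome.length(chrom), np.nan)
              for chrom in genome.chromosomes}

    mode = None            # None | ("fixed", chrom, pos, step, span) | ("var", chrom, span)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            where = f"{path}:{lineno}"
            if line.startswith("fixedStep"):
                kv = _wig_header(line, where)
                chrom = kv["chrom"]
                if chrom not in scores:
                    raise FormatError(f"{where}: unknown chromosome {chrom!r}")
                mode = ["fixed", chrom, int(kv["start"]) - 1,
                        int(kv.get("step", 1)), int(kv.get("span", 1))]
                continue
            if line.startswith("variableStep"):
                kv = _wig_header(line, where)
                chrom = kv["chrom"]
                if chrom not in scores:
                    raise FormatError(f"{where}: unknown chromosome {chrom!r}")
                mode = ["var", chrom, int(kv.get("span", 1))]
                continue
            fields = line.split()
            if len(fields) == 4:  # bedGraph data line
                chrom, start, end, value = fields
                if chrom not in scores:
                    raise FormatError(f"{where}: unknown chromosome {chrom!r}")
                start, end = int(start), int(end)
                _store(scores, chrom, start, end, _score(value, where), where)
                mode = None
                continue
            if mode is None:
                raise FormatError(f"{where}: data line outside wiggle block")
            if mode[0] == "fixed":
                if len(fields) != 1:
                    raise FormatError(f"{where}: fixedStep lines carry one value")
                _, chrom, pos, step, span = mode
                _store(scores, chrom, pos, pos + span, _score(fields[0], where), where)
                mode[2] = pos + step
            else:
                if len(fields) != 2:
                    raise FormatError(f"{where}: variableStep lines carry pos+value")
                _, chrom, span = mode
                pos = int(fields[0]) - 1
                _store(scores, chrom, pos, pos + span, _score(fields[1], where), where)
    return ConservationTrack(scores)


def _wig_header(line: str, where: str) -> dict[str, str]:
    kv = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise FormatError(f"{where}: malformed wiggle header token {tok!r}")
        key, val = tok.split("=", 1)
        kv[key] = val
    if "chrom" not in kv:
        raise FormatError(f"{where}: wiggle header lacks chrom=")
    return kv


def _score(text: str, where: str) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"{where}: non-numeric score {text!r}") from exc
    if not (0.0 <= value <= 1.0):
        raise FormatError(f"{where}: score {value} outside [0,1]")
    return value


def _store(scores, chrom, start, end, value, where):
    arr = scores[chrom]
    if not (0 <= start < end <= arr.size):
        raise FormatError(f"{where}: position [{start},{end}) outside {chrom}")
    arr[start:end] = value


def read_species_bundle(species_id: str, fasta_path: str, annotation_path: str,
                        conservation_path: str, repeat_path: Optional[str] = None,
                        cds_path: Optional[str] = None,
                        chrom_filter: Optional[Callable[[str], bool]] = None):
    """Read one species' full input set into a :class:`SpeciesBundle`.

    The annotation is GFF3 if its suffix is .gff/.gff3, else BED.  When the
    annotation is GFF3 and ``cds_path`` is None, CDS features are taken from
    the same file.
    """
    from .types import SpeciesBundle

    genome = read_fasta(fasta_path, species_id, chrom_filter)
    is_gff = annotation_path.endswith((".gff", ".gff3"))
    if is_gff:
        genes = read_genes_gff3(annotation_path, genome)
    else:
        genes = read_genes_bed(annotation_path, genome)
    track = read_conservation(conservation_path, genome)
    repeat_mask = (read_mask_bed(repeat_path, "repeat", genome)
                   if repeat_path else None)
    if cds_path:
        coding_mask = read_mask_bed(
            cds_path, "coding", genome,
            gff_cds=cds_path.endswith((".gff", ".gff3")))
    elif is_gff:
        coding_mask = read_mask_bed(annotation_path, "coding", genome, gff_cds=True)
    else:
        coding_mask = None
    return SpeciesBundle(species_id, genome, genes, track, repeat_mask, coding_mask)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def seed_table_frame(calls: Iterable[SeedCall]) -> pd.DataFrame:
    rows = [
        (c.seed_7mer, c.site_7mer, c.count_high, c.count_low,
         c.p_raw, c.p_bonferroni, c.is_candidate)
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=SEED_TABLE_COLUMNS)
    return df.sort_values(["p_bonferroni", "seed_7mer"], kind="mergesort",
                          ignore_index=True)


def write_seed_table(calls: Iterable[SeedCall], path: str) -> None:
    """Write the candidate-seed table as TSV, sorted by corrected P then
    lexicographically by seed."""
    df = seed_table_frame(calls)
    df["p_raw"] = df["p_raw"].map(lambda p: format(p, ".6g"))
    df["p_bonferroni"] = df["p_bonferroni"].map(lambda p: format(p, ".6g"))
    df["is_candidate"] = df["is_candidate"].map({True: "True", False: "False"})
    df.to_csv(path, sep="\t", index=False)


def write_target_sites(sites: Iterable[TargetSite], path: str,
                       genome: Optional[GenomeAssembly] = None) -> None:
    """Write target sites as BED6+2 (name=gene|seed, score=round(1000*WCS),
    then site_7mer and WCS columns)."""
    with open(path, "w") as fh:
        for s in sites:
            if genome is not None:
                _check_interval(genome, s.chromosome, s.start, s.end, path)
            score = int(round(1000 * s.wcs))
            fh.write("\t".join([
                s.chromosome, str(s.start), str(s.end),
                f"{s.gene_id}|{s.seed_7mer}", str(score), s.strand,
                s.site_7mer, format(s.wcs, ".6g"),
            ]) + "\n")


def read_target_sites_bed(path: str) -> list[tuple]:
    """Round-trip reader for the BED6+2 target-site output (intervals and
    annotations as written)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 BED6+2 fields")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3],
                        int(fields[4]), fields[5], fields[6], float(fields[7])))
    return out


def write_species_summaries(summaries, path: str) -> None:
    df = pd.DataFrame(
        [(s.species_id, s.n_windows, s.cs50, s.cs95) for s in summaries],
        columns=["species_id", "n_windows", "cs50", "cs95"],
    ).sort_values("species_id", kind="mergesort", ignore_index=True)
    df["cs50"] = df["cs50"].map(lambda v: format(v, ".6g"))
    df["cs95"] = df["cs95"].map(lambda v: format(v, ".6g"))
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
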