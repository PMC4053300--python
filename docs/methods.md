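# Methods

## Model and assumptions

`mirseeds` screens for miRNA seeds by the conservation of their
Watson–Crick 7-mer sites in 3′UTRs across many species. The core
assumptions are:

1. **Defined 3′UTR.** Annotations carry no UTR coordinates, so the 3′UTR
   is the `utr_length` (default 80) nucleotides immediately 3′ of each
   gene's annotated end — genomic-right of the end coordinate for
   plus-strand genes, genomic-left of the start for minus-strand genes —
   clipped at chromosome edges. UTRs overlapping a neighbouring gene's
   ORF are *not* truncated at the seed-calling stage: relative
   conservation rates are unbiased as long as every 7-mer has the same
   chance of landing in coding sequence, while discarding those regions
   would lose genuine seed sites under joint coding + seed constraint.
2. **Window Conservation Score.** Each 7-nt window (step 1, 5′→3′ along
   the UTR sense strand; a clean 80-nt UTR yields 74 windows) is scored
   by the arithmetic mean of its 7 per-base conservation scores. The
   mean is over genomic positions, so WCS is strand-independent. Windows
   containing an `N` base or any missing score, or overlapping a repeat
   interval by ≥ `repeat_overlap_min_bases` (default 1), are dropped
   rather than partially scored — a partial mean would change the
   statistic.
3. **Relative conservation.** Conservation tracks from different species
   come from different alignments and are not comparable in absolute
   value. Each species' WCS list is therefore reduced to ranks: CS50
   (median) and CS95 (95th percentile), computed by linear interpolation
   between closest order statistics (`numpy.percentile` default). Only
   the high/low classification relative to the species' own CS50 is
   pooled.
4. **Binomial null.** Without selective constraint a 7-mer's windows
   fall above or below the within-species median with probability ½.
   Pooled counts (h, l) over all species are tested with the exact
   one-tailed binomial survival function, P(X ≥ h), X ~ Binomial(h+l, ½)
   — no normal approximation, valid for counts up to at least 10⁷.
   Windows whose WCS equals CS50 exactly are excluded from both counts
   so the null probability stays at ½. The median split guarantees the
   marginal ½ only within a species; pooling treats windows as
   independent, which is the method's own approximation. One pooled test
   is performed per 7-mer (not per species).
5. **Multiplicity.** Bonferroni over m tests, candidate iff corrected
   P < α (default 0.05) *and* h > l. `bonferroni_mode="all_kmers"`
   (default) uses m = 4⁷ = 16384; `"observed"` uses the number of
   tallied 7-mers, appropriate for small synthetic genomes where most
   7-mers never occur.
6. **Seed orientation.** The canonical seed–site interaction is
   Watson–Crick pairing, so a conserved site 7-mer is reported as its
   reverse complement (the seed). `seed_orientation="identity"` reports
   the site itself, so comparisons against site-space lists can be run
   both ways.
7. **Overlap significance.** Two seed sets are compared with the
   hypergeometric point mass P_k = C(M,k)·C(N−M,n−k)/C(N,n) summed as an
   inclusive upper tail from the observed overlap. The point mass is
   computed in log space (log-gamma), canonicalized in (M, n) so the
   test is bit-for-bit symmetric in its arguments; the whole-support
   tail (k at or below the minimum feasible overlap) returns exactly 1.
8. **Target genes.** A window becomes a target site iff its seed is a
   candidate, its WCS strictly exceeds its species' CS95 (ties dropped),
   and it overlaps no CDS interval of any gene by even one base; a
   target gene has ≥ 1 surviving site. Per species the package exports
   foreground (target) and background (all annotated) gene-ID lists —
   the inputs a DAVID-style functional enrichment requires; the
   enrichment itself depends on an external, changing knowledge base and
   is out of scope.

## Coordinates and I/O

Internally everything is 0-based half-open. GFF3 (1-based closed) and
wiggle (1-based starts) are converted at the I/O boundary; BED and
bedGraph pass through unchanged. Conservation scores must lie in [0, 1]
(phastCons-like); out-of-range values and malformed lines are rejected
with the offending line number. Missing conservation is explicit (NaN),
never imputed as zero — a base without conservation information is not
an unconserved base. Soft-masked lowercase FASTA is uppercased and *not*
treated as repeat; repeat exclusion comes only from an explicit repeat
BED. Plasmid/scaffold exclusion is a caller-supplied chromosome-name
filter (default: keep every sequence in the FASTA), since no universal
naming rule exists.

## Synthetic-genome generator

`SimConfig` defaults define the reference simulation conditions: 10
species, one 100-kb chromosome each, 200 non-overlapping genes of 300 nt
(consecutive genes ≥ 2×80 nt apart so UTRs never overlap), 5 true seeds
planted with probability 0.2 per (UTR, seed), background per-base scores
i.i.d. Beta with mean 0.3 and concentration 8, planted-site scores Beta
with mean 0.95 and concentration 50. The Beta(mean, concentration)
parameterization was chosen as a bounded two-parameter family on [0, 1]
with a realistic phastCons-like spread; only the high/low contrast
matters to the test. All randomness flows from one integer seed through
`numpy` `SeedSequence` spawning, so a config reproduces byte-identical
bundles and files.

Planting writes the seed's reverse complement at a uniformly chosen UTR
offset on the sense strand (strand-aware on the genome) and redraws the
7 bases' scores from the planted distribution. Two generator-specific
design choices matter for interpretation:

* **Flank masking** (`mask_flank_scores=True`). High planted scores
  bleed into windows that overlap a planted site by 1–6 nt, which would
  make the site's *shifted* 7-mers significant as well — a positional
  leakage effect that real conserved elements also produce. The
  generator marks the 6 bases flanking each planted site as missing, so
  the pipeline's own missing-score rule drops partially overlapping
  windows and the simulation measures seed-level recovery in isolation.
  Plantings within one UTR are kept ≥ 6 nt apart for the same reason.
  Consequently, passing recovery tests demonstrate correct seed-level
  inference, *not* robustness to shifted-motif artifacts in real data
  (see Limitations).
* **Repeats and planted sites.** Random repeat intervals
  (`repeat_frac` of the genome, default 0) are placed away from planted
  sites so repeat exclusion can be tested independently; the adversarial
  `plant_in_repeats=True` scenario instead marks the planted sites
  themselves as repeats and expects non-recovery.

What the generator does **not** emulate: realistic base composition or
codon structure, phylogenetically correlated conservation (scores are
i.i.d. given the planted/background label), alignment artifacts,
overlapping genes, or UTR length variation. Passing tests therefore
validate the pipeline's statistical machinery and plumbing, not its
behaviour on real archaeal tracks.

## Test problem sizes

The verification suite uses scaled simulations chosen to exercise the
statistics with comfortable margins: family-wise error control is
measured on 100 independent null bundles of 3 species × 40 genes × 20 kb
(FWER control is size-free, so small bundles suffice); seed recovery is
measured on 20 replicates at the full reference conditions above; the
shared integration fixture uses 3 species × 40 genes with planting
probability 0.5 (a strong effect, since ~24 expected plantings per seed
would sit exactly at the Bonferroni detection boundary and make a
deterministic fixture flaky).

## Numerical choices

* Binomial tail via `scipy.stats.binom.sf` (exact survival function);
  the test suite pins it against rational brute-force pmf sums for all
  tallies with n ≤ 25.
* Hypergeometric tail pinned against exhaustive draw enumeration for
  universes N ≤ 12 and against `scipy.stats.hypergeom` at genome scale.
* Percentiles: linear interpolation (documented, fixed); with all-equal
  scores every window ties CS50, every test is skipped, and no
  candidates are produced (degenerate input handled, not an error).
* Ties: WCS = CS50 excluded from the binomial counts; WCS = CS95
  excluded from target sites (strict inequalities).
* Zero-length UTRs (gene abuts the chromosome edge) are logged and
  excluded; a species with no retained windows is dropped with a
  warning; zero species retained is a hard error.
* BED score column: `round(1000 × WCS)` (banker's rounding, the Python
  default).

## Known limitations

* The 80-nt UTR definition is a heuristic; genes with genuinely longer
  or shorter UTRs are mis-windowed, and sensitivity depends on
  annotation quality.
* Perfect 7-mer matching only: wobble (G:U) or mismatch-tolerant seed
  pairing is outside the method.
* Shifted-7-mer leakage around truly conserved elements is real in
  genomic data and is deliberately removed from the simulation (flank
  masking); on real tracks, clusters of overlapping candidate 7-mers
  should be expected and post-processed.
* Pooling counts across species ignores phylogenetic non-independence;
  closely related species contribute pseudo-replicated evidence.
* Bonferroni is conservative for 16,384 discrete tests; no FDR
  alternative is provided.
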