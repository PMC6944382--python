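# Methods

## Scope and data model

`retroquant` quantifies retrotransposon expression from already-aligned
RNA-seq reads. It consumes coordinate-sorted SAM/BAM with mismatch tags
(`nM` as written by STAR, `NM` as written by samtools-compatible tools),
`NH` hit counts and primary/secondary flags; RepeatMasker-style repeat
annotations (BED6 or `.out`); gene bodies from a GTF; and a
subfamily→group CSV. Alignment itself, gene-level differential expression
and annotation construction are out of scope.

All coordinates are converted to a single internal convention — 0-based,
half-open — at import: BED is taken as-is, GTF and RepeatMasker `.out`
(1-based inclusive) have their starts shifted by −1. One convention
everywhere removes the usual off-by-one drift between formats; abutting
half-open intervals do not overlap.

## Perfect-mapping policy

The counting unit is one mate of one fragment, `(read_id, mate_index)`.
Treating mates independently handles 50 nt single-end, 75 nt and 125 nt
paired-end libraries uniformly; fragment-level counting would silently
halve paired-end counts relative to single-end.

An alignment is *perfect* when its mismatch tag is 0. Tags are consulted in
a configurable priority order (`nM` before `NM` by default, since `nM` is
the spliced-aligner substitution count while `NM` also counts indel bases);
a record carrying none of the tags is a hard error naming the read — a
silent guess would corrupt every downstream number in an unobservable way.
The default strict policy additionally rejects insertions, deletions and
soft-clipped bases even at mismatch 0 ("no substitutions or indels"); a
tag-only policy is available for data where clipping is expected. Splice
skips (CIGAR `N`) are permitted by default because spliced aligners emit
them for genuinely perfect reads.

Library size for RPM scaling is the number of **distinct read units with at
least one perfect alignment** — a multimapper counts once regardless of how
many records it carries. Whether to count units or alignments is a genuine
fork; units were chosen because the alternative would make library size
depend on the aligner's reporting limit for multimappers.

## Counting algorithm

For each perfect alignment, every retained repeat locus that completely
contains it (all aligned bases, and by default the splice gaps as well,
inside `[start, end)`) yields a pair `(read_unit, unit_label)` where the
label is the locus's subfamily or group. Raw counts are the number of
distinct pairs. This set semantics gives, for free:

- multimapper deduplication within a subfamily (the stated rule);
- at group level, deduplication by `(read_unit, group)` — the natural lift
  of the subfamily rule, so a unit hitting two subfamilies of one group
  counts once for the group (the subfamily rule only defines the
  within-subfamily case; the lift is our choice and is documented here);
- invariance to input order and to duplicated records;
- a unit contained in loci of two different subfamilies contributes once to
  each (nested annotations are retained, not resolved).

Spliced reads whose gap bridges outside the locus are excluded by default
(strict containment of the outer span); a block-wise mode relaxes this.
Strictness is the conservative choice for repeat-internal reads, where a
splice out of the element usually means the read belongs to a host
transcript.

Gene masking drops a repeat locus on ≥ 1 bp overlap with any gene body,
both strands, all biotypes (a biotype filter is available). Gene bodies
rather than exons, and strand-agnostic overlap, are the most literal
reading of "overlapping with genes"; an intronic repeat read is
indistinguishable from pre-mRNA signal, so the aggressive mask is the safe
default.

Normalization: `rpm = raw · 10⁶ / library`, `rpkm = rpm / (retained
annotated kb of the unit)`. RPKM uses retained (post-mask) lengths so the
numerator and denominator describe the same territory. Units with zero
retained length are an error rather than an infinity.

## Comparisons

- **Fold change**: per unit, all m×n pairwise log2 ratios between the
  replicates of two conditions, with pseudocount 0.1 RPM added to both
  sides; the median (mean-of-middle-two for even counts) is reported. The
  median over pairs is robust to one outlying replicate and antisymmetric
  under swapping conditions. 0.1 RPM is small against any signal of
  interest but keeps zero-count units finite; it is configurable and
  recorded in output headers.
- **Relative-to-control ratios** on aggregated (mean-RPM) tables use the
  same pseudocount.
- **Correlation matrices** are computed on per-unit RPKM vectors, Pearson
  by default on untransformed values (the minimal reading of the
  procedure); Spearman and a uniform log2(x+pc) transform are offered
  because the choice is not determined.
- **Relative expression matrix** for stage heatmaps scales each unit's row
  by its maximum across stages; all-zero rows stay zero. Row-max scaling is
  an explicit stand-in for a heatmap recipe that is not fully specified.

## Locus-level coverage

Per locus: per-base depth from the aligned blocks of every perfect
alignment, primary or secondary — retaining multimappers is the point, the
question being whether piled-up multimapping signal is corroborated by
contiguous coverage. Metrics: percent of positions with depth ≥
`min_depth` (default 1), longest contiguous run at that threshold, distinct
perfect read units overlapping the locus, and flank read-through — the run
of covered bases contiguous with each element edge within a `flank_bp`
window (default 500 bp, genomic orientation). `min_depth` and the flank
window are interpretation choices exposed as flags; the qualitative notion
of "read-through" needs an explicit window to be computable. Paired mates
contribute blocks independently; the unsequenced inner insert is not
imputed, because imputation would fabricate covered bases.

Candidate expressed elements are ranked by the deterministic key
(pct_covered desc, reads_in_locus desc, longest_run desc, locus_id asc) —
coverage first, because read count alone is dominated by multimapping
pile-up. bedGraph export run-length-encodes the depth profile (zero runs
omitted), optionally scaled to CPM (depth · 10⁶ / perfect units) so tracks
from different libraries share a scale.

## Small-RNA spectra and the siRNA-target filter

Length histograms use **primary alignments only** (one record per read) and
attribute an alignment to every group whose loci it overlaps by ≥ 1 bp —
attribution, not containment, because small RNAs are far shorter than the
elements they derive from; this deliberately diverges from the mRNA
counting rule. Read length is the sequenced length (adapters assumed
trimmed), histogram range 18–32 nt by default, out-of-range reads tallied
rather than dropped. Up to one mismatch is admitted by default, mirroring
typical small-RNA mapping tolerance; a strict flag restricts to perfect.

The siRNA-target filter counts primary, perfect, 21–23 nt alignments
overlapping a gene body on the opposite strand, scales to RPM per library,
averages across libraries (per-library RPM first, then the mean — the
averaging order is our choice), and passes a gene iff the average is
**strictly greater** than 50 RPM. Identifying the dsRNA origin of the
siRNAs is curation beyond the filter; calls carry
`origin_identified="unknown"`.

## Synthetic data generator

The simulator emits alignment records directly rather than FASTQ through an
aligner, so multimapping structure, tags and flags are exactly controlled
and the truth table is exact by construction. What it emulates:

- repeat subfamilies with several genomic copies, the first `n_identical`
  of each byte-identical — a read drawn from one is emitted once per
  identical copy with `NH` set and exactly one primary record;
- a configured fraction of repeat copies embedded in gene bodies (these are
  the loci gene masking must remove); unique copies are embedded
  preferentially so multimapping families keep retained members;
- per-condition, per-subfamily expression (reads per copy, Poisson), with
  the default conditions planting a 6× L1Md_T derepression, 3× RLTR10 and
  1.2× IAP in a double-mutant versus control, three replicates each, 75 nt
  paired-end;
- a fraction of mates carrying one substitution (`nM=1`) or a 2 bp indel
  (`nM=0`, `NM=2` — substitution tags exclude indel bases, edit-distance
  tags include them), exercising the policy paths;
- sequencing depth fixed per sample (default 4,000 fragments): background
  genic fragments fill each condition to the same expected total, because
  depth is set by the instrument, not by repeat biology — without this,
  strong derepression would shift every RPM through the library-size
  denominator and the planted fold changes would not be recoverable on the
  RPM scale;
- small-RNA libraries with per-group length mixtures (MaLR-derived reads
  60% in 21–23 nt, IAP 90% in 25–30 nt), genes with antisense 22 nt reads
  planted at exact RPM values, and intergenic filler up to an exact library
  size. The default library of 100,000 units is the smallest in which both
  a 60 RPM and an exactly-50 RPM antisense gene are integer read counts,
  so the strict > 50 boundary is testable exactly.

What it does **not** emulate: sequencing errors and quality variation,
transcript splicing, fragment-length biases, adapter artifacts, annotation
errors, and diverged-copy mismatch structure beyond the single planted
substitution. Passing tests therefore demonstrate algorithmic correctness
(counting, deduplication, masking, normalization, metric arithmetic) under
controlled multimapping — not robustness to every artifact of real
libraries.

The truth table records, per sample, the exact deduplicated subfamily and
group counts, library sizes, per-locus depth vectors, planted fold changes
and planted antisense RPM implied by the emitted records. Everything is
deterministic under (config, seed); fixtures are generated at test time,
never stored.

## Numerical and degenerate-input choices

- Zero-library RPM, zero-length RPKM units, non-positive pseudocounts and
  zero-variance correlation vectors are errors, never silent NaN/inf.
- Empty repeat annotations produce an all-zero table with a warning; units
  absent from a replicate enter aggregation and fold changes as RPM 0.
- Ranking, table ordering and file output are fully deterministic
  (sorted units, stable sort keys), so identical inputs give byte-identical
  outputs.
- Hard-clipped bases are treated like soft-clips by the strict policy.

## Problem sizes

The test suite and the acceptance script run on simulated datasets of
roughly 2,000–50,000 alignment records per sample (20 seeded datasets for
the counting-oracle comparison, 10–20 seeds for fold-change recovery, a
100,000-unit small-RNA library for the filter boundary), sizes at which
exact brute-force oracles remain feasible while every code path —
multimapping, masking, splicing, indels, both layouts — is exercised.

## Known limitations

- No EM-style fractional assignment of multimappers across subfamilies
  (TEtranscripts-like); the deduplicated-count model is the method here.
- Gene-level differential expression, significance testing for repeat
  units, and PCA are out of scope.
- The `--threads` flag is reserved; processing is single-threaded (outputs
  are guaranteed independent of thread count by construction).
- RepeatMasker `.out` parsing covers the standard column layout only.
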