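"""Synthetic toy genome, annotations and alignment simulator.

The simulator builds a small single-chromosome genome carrying repeat
copies of several subfamilies (some byte-identical, so reads drawn from
them necessarily multimap), gene bodies (a configured fraction of repeat
copies is embedded in genes and therefore subject to gene masking), and
emits per-sample SAM files together with a machine-readable truth table:
the exact deduplicated per-subfamily counts, library sizes and per-locus
depth vectors implied by the emitted records, plus the planted
per-subfamily fold changes between conditions.

Alignment records are emitted directly (not FASTQ through an aligner) so
multimapping structure, mismatch tags and flags are exactly controlled: a
read from an n-identical-copy family yields one record per identical copy
with ``NH=n`` and exactly one primary.  Mismatch reads carry ``nM=1``;
indel reads carry an indel CIGAR with ``nM=0`` (STAR-style: the tag counts
substitutions) and ``NM=2`` (samtools-style: the tag counts edited bases).

The default configuration mirrors the study conditions the pipeline is
meant for: 75 nt paired-end libraries, three biological replicates per
condition, a control and a double-mutant condition with a planted six-fold
L1Md_T derepression, smaller RLTR10 and IAP effects, and small-RNA
libraries whose length mixtures contrast a 21-23 nt (siRNA) mode over
MaLR/MT elements with a 25-30 nt (piRNA) mode over IAP.

Everything is deterministic under (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .annotations import GeneFeature, GroupMap, RepeatLocus, write_bed

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SubfamilySpec:
    """One simulated repeat subfamily.

    The first ``n_identical`` copies share byte-identical sequence; the
    rest diverge (independent random sequence).
    """

    subfamily: str
    group: str
    n_copies: int
    copy_length: int
    n_identical: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.n_identical <= self.n_copies:
            raise ValueError(
                f"{self.subfamily}: need 1 <= n_identical <= n_copies"
            )


DEFAULT_SPECS: tuple[SubfamilySpec, ...] = (
    SubfamilySpec("L1Md_T", "L1", n_copies=4, copy_length=1500, n_identical=3),
    SubfamilySpec("IAPEz-int", "IAP", n_copies=3, copy_length=1200, n_identical=2),
    SubfamilySpec("RLTR10", "ERVK", n_copies=3, copy_length=600, n_identical=2),
    SubfamilySpec("MTA_Mm", "MaLR", n_copies=3, copy_length=500, n_identical=2),
)

# Reads per copy per condition.  double_mutant plants a 6x L1Md_T
# derepression, a 3x RLTR10 and a mild 1.2x IAP effect over control.
DEFAULT_EXPRESSION: dict[str, dict[str, float]] = {
    "control": {"L1Md_T": 30.0, "IAPEz-int": 40.0, "RLTR10": 30.0, "MTA_Mm": 30.0},
    "double_mutant": {
        "L1Md_T": 180.0,
        "IAPEz-int": 48.0,
        "RLTR10": 90.0,
        "MTA_Mm": 30.0,
    },
}

# Small-RNA length mixtures per group: MaLR-derived small RNAs are
# siRNA-like (60% of mass at 21-23 nt), IAP piRNA-like (90% at 25-30 nt).
DEFAULT_SMALLRNA_MIXTURES: dict[str, dict[int, float]] = {
    "MaLR": {21: 0.15, 22: 0.30, 23: 0.15, 26: 0.10, 27: 0.10, 28: 0.10, 29: 0.05, 30: 0.05},
    "IAP": {22: 0.10, 26: 0.20, 27: 0.25, 28: 0.25, 29: 0.15, 30: 0.05},
    "L1": {22: 0.20, 26: 0.20, 27: 0.20, 28: 0.20, 29: 0.10, 30: 0.10},
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom: str = "chr1"
    genome_length: int = 250_000
    subfamily_specs: tuple[SubfamilySpec, ...] = DEFAULT_SPECS
    n_genes: int = 6
    gene_length: int = 4000
    fraction_repeats_in_genes: float = 0.2
    expression: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EXPRESSION.items()}
    )
    replicates: int = 3
    # Sequencing depth is set by the instrument, not by repeat biology: with
    # total_fragments set, background (genic) fragments fill each sample up
    # to the same expected fragment total in every condition, so RPM fold
    # changes reflect the planted per-copy expression ratios.  With
    # total_fragments None, a fixed background_reads count is used instead.
    total_fragments: int | None = 4000
    background_reads: int = 2000
    mismatch_fraction: float = 0.08
    indel_fraction: float = 0.04
    layout: str = "PE75"  # SE50 | PE75 | PE125
    smallrna_mixtures: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SMALLRNA_MIXTURES.items()
        }
    )
    smallrna_reads_per_group: int = 600
    smallrna_library_size: int = 100_000
    # (gene index, planted antisense 21-23 nt RPM); defaults bracket the
    # 50 RPM candidate threshold from both sides
    antisense_genes: tuple[tuple[int, float], ...] = ((0, 60.0), (1, 50.0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_repeats_in_genes <= 1.0:
            raise ValueError("fraction_repeats_in_genes must be in [0,1]")
        if not 0.0 <= self.mismatch_fraction + self.indel_fraction <= 1.0:
            raise ValueError("mismatch + indel fractions must be in [0,1]")
        for group, mix in self.smallrna_mixtures.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"small-RNA mixture for {group} sums to {total}")
        if self.layout not in ("SE50", "PE75", "PE125"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def read_length(self) -> int:
        return {"SE50": 50, "PE75": 75, "PE125": 125}[self.layout]

    @property
    def paired(self) -> bool:
        return self.layout.startswith("PE")


@dataclass
class ToyReference:
    """Toy genome plus annotations produced by :func:`build_toy_reference`."""

    chrom: str
    genome: str
    repeats: list[RepeatLocus]  # groups assigned
    genes: list[GeneFeature]
    group_map: GroupMap
    in_gene_locus_ids: frozenset[str]
    config: SyntheticConfig

    @property
    def retained(self) -> list[RepeatLocus]:
        return [r for r in self.repeats if r.locus_id not in self.in_gene_locus_ids]

    def family_copies(self, subfamily: str) -> list[RepeatLocus]:
        return [r for r in self.repeats if r.subfamily == subfamily]


@dataclass
class SyntheticTruth:
    """Planted expectations, exactly consistent with the emitted files."""

    subfamily_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    group_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    library_sizes: dict[str, int] = field(default_factory=dict)
    total_units: dict[str, int] = field(default_factory=dict)
    locus_depth: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    antisense_rpm: dict[str, dict[str, float]] = field(default_factory=dict)
    smallrna_length_counts: dict[str, dict[str, dict[int, int]]] = field(
        default_factory=dict
    )

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with Path(path).open() as fh:
            data = json.load(fh)
        truth = cls(**data)
        truth.smallrna_length_counts = {
            s: {g: {int(l): c for l, c in hist.items()} for g, hist in groups.items()}
            for s, groups in truth.smallrna_length_counts.items()
        }
        return truth


# ---------------------------------------------------------------------------
# reference construction


def build_toy_reference(config: SyntheticConfig) -> ToyReference:
    """Place genes and repeat copies on a seeded random genome.

    Layout is deterministic given the config: genes first, then
    non-embedded repeat copies in intergenic space.  Exactly
    ``round(fraction_repeats_in_genes * n_copies_total)`` copies are
    embedded inside gene bodies, preferring the non-identical (unique)
    copies so that multimapping families keep retained members.
    """
    specs = config.subfamily_specs
    n_total = sum(s.n_copies for s in specs)
    n_in_gene = int(round(config.fraction_repeats_in_genes * n_total))

    genes: list[GeneFeature] = []
    cursor = 1000
    for i in range(config.n_genes):
        genes.append(
            GeneFeature(
                gene_id=f"gene{i}",
                chrom=config.chrom,
                start=cursor,
                end=cursor + config.gene_length,
                strand="+" if i % 2 == 0 else "-",
                biotype="protein_coding",
            )
        )
        cursor += config.gene_length + 800

    # choose embedded copies: walk families round-robin from their last
    # (unique) copy backwards
    embedded: set[tuple[int, int]] = set()
    offset = 0
    while len(embedded) < n_in_gene:
        progressed = False
        for fi, spec in enumerate(specs):
            idx = spec.n_copies - 1 - offset
            if idx >= 0 and len(embedded) < n_in_gene:
                embedded.add((fi, idx))
                progressed = True
        if not progressed:
            raise ValueError("fraction_repeats_in_genes exceeds available copies")
        offset += 1

    placements: dict[tuple[int, int], int] = {}
    gene_used = [200] * config.n_genes  # next free offset inside each gene
    gi = 0
    for fi, spec in enumerate(specs):
        for ci in range(spec.n_copies):
            if (fi, ci) not in embedded:
                continue
            placed = False
            for attempt in range(config.n_genes):
                g = (gi + attempt) % config.n_genes
                if gene_used[g] + spec.copy_length + 100 <= config.gene_length:
                    placements[(fi, ci)] = genes[g].start + gene_used[g]
                    gene_used[g] += spec.copy_length + 150
                    gi = (g + 1) % config.n_genes
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"cannot embed {spec.subfamily} copy {ci} in any gene body"
                )
    for fi, spec in enumerate(specs):
        for ci in range(spec.n_copies):
            if (fi, ci) in placements:
                continue
            placements[(fi, ci)] = cursor
            cursor += spec.copy_length + 500
    if cursor + 100 > config.genome_length:
        raise ValueError(
            f"placements need {cursor + 100} bp, genome_length is "
            f"{config.genome_length}"
        )

    rng = np.random.default_rng([config.seed, 7])
    genome = rng.choice(_BASES, size=config.genome_length)
    # enforce byte-identity of the identical copy sets
    for fi, spec in enumerate(specs):
        master = placements[(fi, 0)]
        for ci in range(1, spec.n_identical):
            start = placements[(fi, ci)]
            genome[start : start + spec.copy_length] = genome[
                master : master + spec.copy_length
            ]

    gmap = GroupMap({s.subfamily: s.group for s in specs})
    repeats = []
    in_gene_ids = set()
    for fi, spec in enumerate(specs):
        for ci in range(spec.n_copies):
            start = placements[(fi, ci)]
            locus = RepeatLocus(
                locus_id=f"{spec.subfamily}_{ci}",
                chrom=config.chrom,
                start=start,
                end=start + spec.copy_length,
                strand="+",
                subfamily=spec.subfamily,
                group=spec.group,
            )
            repeats.append(locus)
            if (fi, ci) in embedded:
                in_gene_ids.add(locus.locus_id)
    repeats.sort(key=lambda r: (r.start, r.locus_id))
    return ToyReference(
        chrom=config.chrom,
        genome="".join(genome),
        repeats=repeats,
        genes=genes,
        group_map=gmap,
        in_gene_locus_ids=frozenset(in_gene_ids),
        config=config,
    )


def write_reference(ref: ToyReference, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA / BED6 / GTF / group CSV / L1-style locus CSV files."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "genome.fa",
        "repeats_bed": out_dir / "repeats.bed",
        "genes_gtf": out_dir / "genes.gtf",
        "groups_csv": out_dir / "groups.csv",
        "l1_csv": out_dir / "l1_full_length.csv",
    }
    SeqIO.write(
        [SeqRecord(Seq(ref.genome), id=ref.chrom, description="synthetic toy genome")],
        paths["fasta"],
        "fasta",
    )
    write_bed(ref.repeats, paths["repeats_bed"])
    with paths["genes_gtf"].open("w") as fh:
        for g in ref.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
    ref.group_map.to_csv(paths["groups_csv"])
    l1 = [r for r in ref.repeats if r.group == "L1"]
    with paths["l1_csv"].open("w") as fh:
        fh.write("locus_id,chrom,start,end,strand,subfamily\n")
        for r in l1:
            fh.write(
                f"{r.locus_id},{r.chrom},{r.start},{r.end},{r.strand},{r.subfamily}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# alignment emission helpers


def _sam_header(ref: ToyReference) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.chrom, "LN": len(ref.genome)}],
    }


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    flag: int,
    pos: int,
    cigar: str,
    seq: str,
    nh: int,
    nm_lower: int,
    nm_upper: int,
    mate_pos: int | None = None,
    tlen: int = 0,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = flag
    seg.reference_id = 0
    seg.reference_start = pos
    seg.mapping_quality = 255
    seg.cigarstring = cigar
    if mate_pos is not None:
        seg.next_reference_id = 0
        seg.next_reference_start = mate_pos
        seg.template_length = tlen
    seg.query_sequence = seq
    seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    seg.set_tags([("NH", nh), ("nM", nm_lower), ("NM", nm_upper)])
    return seg


def _write_sam(
    segments: list[pysam.AlignedSegment], header: dict, path: Path
) -> None:
    segments.sort(key=lambda s: (s.reference_start, s.query_name, s.flag))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for seg in segments:
            fh.write(seg)


def _gene_free_intervals(ref: ToyReference, min_len: int) -> list[list[tuple[int, int]]]:
    """Per-gene subintervals clear of embedded repeats (10 bp margins)."""
    out = []
    for gene in ref.genes:
        blockers = sorted(
            (r.start, r.end)
            for r in ref.repeats
            if r.locus_id in ref.in_gene_locus_ids
            and r.start < gene.end
            and r.end > gene.start
        )
        free = []
        pos = gene.start
        for bs, be in blockers:
            if bs - 10 - pos >= min_len:
                free.append((pos, bs - 10))
            pos = max(pos, be + 10)
        if gene.end - pos >= min_len:
            free.append((pos, gene.end))
        out.append(free)
    return out


def _read_seq(
    genome: str, pos: int, read_len: int, category: str, rng: np.random.Generator
) -> tuple[str, str, int, int, int]:
    """Sequence, CIGAR, reference span and mismatch tags for one mate.

    category: "perfect" | "mismatch" | "del" | "ins".
    Returns (seq, cigar, ref_span, nM, NM).
    """
    if category == "perfect":
        return genome[pos : pos + read_len], f"{read_len}M", read_len, 0, 0
    if category == "mismatch":
        seq = list(genome[pos : pos + read_len])
        p = int(rng.integers(read_len))
        seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
        return "".join(seq), f"{read_len}M", read_len, 1, 1
    if category == "del":
        a = 20
        seq = genome[pos : pos + a] + genome[pos + a + 2 : pos + read_len + 2]
        return seq, f"{a}M2D{read_len - a}M", read_len + 2, 0, 2
    if category == "ins":
        a = 20
        seq = genome[pos : pos + a] + "AC" + genome[pos + a : pos + read_len - 2]
        return seq, f"{a}M2I{read_len - 22}M", read_len - 2, 0, 2
    raise ValueError(category)


def _draw_category(rng: np.random.Generator, config: SyntheticConfig) -> str:
    u = rng.random()
    if u < config.mismatch_fraction:
        return "mismatch"
    if u < config.mismatch_fraction + config.indel_fraction:
        return "del" if rng.random() < 0.5 else "ins"
    return "perfect"


# ---------------------------------------------------------------------------
# mRNA-seq simulation


def simulate_alignments(
    config: SyntheticConfig,
    ref: ToyReference,
    out_dir: str | Path,
    conditions: Sequence[str] | None = None,
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Emit per-sample coordinate-sorted SAM files plus the truth table.

    Per condition and replicate, each repeat copy receives a Poisson number
    of fragments at the configured per-copy expectation; fragments from an
    identical-copy set are emitted once per identical copy (NH set, one
    primary at the source copy).  Background fragments fall in repeat-free
    gene space so the library size exceeds the repeat-derived counts, as in
    a real library.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = list(conditions or config.expression.keys())
    header_dict = _sam_header(ref)
    header = pysam.AlignmentHeader.from_dict(header_dict)
    truth = SyntheticTruth()
    base_cond = conditions[0]
    for cond in conditions:
        truth.fold_changes[cond] = {}
        for spec in config.subfamily_specs:
            num = config.expression.get(cond, {}).get(spec.subfamily, 0.0)
            den = config.expression.get(base_cond, {}).get(spec.subfamily, 0.0)
            truth.fold_changes[cond][spec.subfamily] = (
                num / den if den > 0 else float("nan")
            )

    specs = config.subfamily_specs
    copies_by_family = {s.subfamily: ref.family_copies(s.subfamily) for s in specs}
    rl = config.read_length
    free_by_gene = _gene_free_intervals(ref, min_len=2 * rl + 120)
    usable_genes = [i for i, free in enumerate(free_by_gene) if free]
    if (config.total_fragments is not None or config.background_reads) and not usable_genes:
        raise ValueError("no repeat-free gene space for background reads")

    sam_paths: dict[str, Path] = {}
    for ci, cond in enumerate(conditions):
        expected_repeat_frags = sum(
            config.expression.get(cond, {}).get(s.subfamily, 0.0) * s.n_copies
            for s in specs
        )
        if config.total_fragments is not None:
            n_background = int(round(config.total_fragments - expected_repeat_frags))
            if n_background < 0:
                raise ValueError(
                    f"condition {cond}: expected repeat fragments "
                    f"({expected_repeat_frags:.0f}) exceed total_fragments "
                    f"({config.total_fragments})"
                )
        else:
            n_background = config.background_reads
        for rep in range(1, config.replicates + 1):
            sample = f"{cond}_rep{rep}"
            rng = np.random.default_rng([config.seed % (2**31), 101, ci, rep])
            segments: list[pysam.AlignedSegment] = []
            sub_units: dict[str, set] = {s.subfamily: set() for s in specs}
            grp_units: dict[str, set] = {s.group: set() for s in specs}
            depth = {
                r.locus_id: np.zeros(r.length, dtype=np.int64) for r in ref.repeats
            }
            n_perfect_units = 0
            n_total_units = 0
            serial = 0

            def emit_fragment(
                targets: list[RepeatLocus] | None,
                primary_locus: RepeatLocus | None,
                abs_start: int,
                region_len_left: int,
            ) -> None:
                """Emit one fragment (both mates if paired) at abs_start.

                ``targets`` lists the identical copies to replicate the
                records at (None for unique placement);
                ``region_len_left`` bounds the fragment so every record
                stays inside its region.
                """
                nonlocal serial, n_perfect_units, n_total_units
                serial += 1
                name = f"{sample}:{serial:07d}"
                if config.paired:
                    frag = int(rng.integers(2 * rl + 10, 2 * rl + 101))
                    frag = min(frag, region_len_left - 2)
                    rel = int(rng.integers(0, region_len_left - frag - 1))
                    fwd = rng.random() < 0.5
                    mates = [
                        (1, rel, not fwd),
                        (2, rel + frag - rl, fwd),
                    ]
                else:
                    frag = rl
                    rel = int(rng.integers(0, region_len_left - frag - 1))
                    mates = [(0, rel, rng.random() < 0.5)]
                rel_base = abs_start - (
                    primary_locus.start if primary_locus is not None else 0
                )
                mate_info = []
                for mate_index, mrel, reverse in mates:
                    category = _draw_category(rng, config)
                    mate_info.append((mate_index, mrel, reverse, category))
                    n_total_units += 1
                    if category == "perfect":
                        n_perfect_units += 1
                target_loci = targets if targets is not None else [None]
                nh = len(target_loci)
                for t_idx, locus in enumerate(target_loci):
                    if locus is None:
                        t_start = abs_start
                    else:
                        t_start = locus.start + rel_base
                    is_primary = locus is primary_locus or locus is None
                    for mi, (mate_index, mrel, reverse, category) in enumerate(
                        mate_info
                    ):
                        pos = t_start + mrel
                        seq, cigar, span, nm_lo, nm_hi = _read_seq(
                            ref.genome, pos, rl, category,
                            np.random.default_rng([config.seed % (2**31), 9, serial, mi]),
                        )
                        flag = 0
                        if mate_index:
                            other = mate_info[1 - mi]
                            flag |= 0x1 | 0x2
                            flag |= 0x40 if mate_index == 1 else 0x80
                            if reverse:
                                flag |= 0x10
                            if other[2]:
                                flag |= 0x20
                            mate_pos = t_start + other[1]
                            tlen = frag if mrel <= other[1] else -frag
                        else:
                            if reverse:
                                flag |= 0x10
                            mate_pos, tlen = None, 0
                        if not is_primary:
                            flag |= 0x100
                        segments.append(
                            _make_segment(
                                header, name, flag, pos, cigar, seq, nh,
                                nm_lo, nm_hi, mate_pos, tlen,
                            )
                        )
                        if category == "perfect" and locus is not None:
                            d = depth[locus.locus_id]
                            a = max(0, pos - locus.start)
                            b = min(locus.length, pos + span - locus.start)
                            if a < b:
                                d[a:b] += 1
                # truth counting: a perfect mate counted once per subfamily
                # with >=1 retained containing copy
                if target_loci[0] is not None:
                    retained_targets = [
                        l
                        for l in target_loci
                        if l.locus_id not in ref.in_gene_locus_ids
                    ]
                    if retained_targets:
                        sf = target_loci[0].subfamily
                        grp = target_loci[0].group
                        for mate_index, _, _, category in mate_info:
                            if category == "perfect":
                                sub_units[sf].add((name, mate_index))
                                grp_units[grp].add((name, mate_index))

            for spec in specs:
                lam = config.expression.get(cond, {}).get(spec.subfamily, 0.0)
                copies = copies_by_family[spec.subfamily]
                identical = copies_by_family[spec.subfamily]
                identical_set = [
                    c for c in copies if int(c.locus_id.rsplit("_", 1)[1]) < spec.n_identical
                ]
                for copy in copies:
                    n = int(rng.poisson(lam)) if lam > 0 else 0
                    in_identical = copy in identical_set
                    targets = identical_set if in_identical else [copy]
                    for _ in range(n):
                        emit_fragment(targets, copy, copy.start, copy.length)

            for _ in range(n_background):
                g = usable_genes[int(rng.integers(len(usable_genes)))]
                free = free_by_gene[g]
                s, e = free[int(rng.integers(len(free)))]
                emit_fragment(None, None, s, e - s)

            path = out_dir / f"{sample}.sam"
            _write_sam(segments, header_dict, path)
            sam_paths[sample] = path
            truth.subfamily_counts[sample] = {
                sf: len(units) for sf, units in sub_units.items()
            }
            truth.group_counts[sample] = {
                g: len(units) for g, units in grp_units.items()
            }
            truth.library_sizes[sample] = n_perfect_units
            truth.total_units[sample] = n_total_units
            truth.locus_depth[sample] = {
                lid: vec.tolist() for lid, vec in depth.items()
            }
    return sam_paths, truth


# ---------------------------------------------------------------------------
# small-RNA simulation


def simulate_smallrna(
    config: SyntheticConfig,
    ref: ToyReference,
    out_dir: str | Path,
    sample_id: str = "smallrna_rep1",
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Emit one small-RNA SAM library plus its truth table.

    Group reads draw their lengths from the configured per-group mixture
    and fall inside non-embedded loci of the group (identical copies
    multimap as in the mRNA simulator; only one record is primary).
    Antisense reads are planted on the opposite strand of chosen genes at
    exact RPM values; the rest of the library is intergenic filler so the
    library size is exactly ``smallrna_library_size`` perfect read units.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed % (2**31), 202])
    header_dict = _sam_header(ref)
    header = pysam.AlignmentHeader.from_dict(header_dict)
    segments: list[pysam.AlignedSegment] = []
    truth = SyntheticTruth()
    length_counts: dict[str, dict[int, int]] = {}
    serial = 0
    n_emitted_units = 0

    def emit_single(
        pos: int, length: int, reverse: bool, nh: int, primary: bool, name: str
    ) -> None:
        flag = (0x10 if reverse else 0) | (0 if primary else 0x100)
        seq = ref.genome[pos : pos + length]
        segments.append(
            _make_segment(header, name, flag, pos, f"{length}M", seq, nh, 0, 0)
        )

    group_copies: dict[str, list[RepeatLocus]] = {}
    for r in ref.repeats:
        if r.locus_id not in ref.in_gene_locus_ids:
            group_copies.setdefault(r.group, []).append(r)
    spec_by_subfamily = {s.subfamily: s for s in config.subfamily_specs}

    for group in sorted(config.smallrna_mixtures):
        mix = config.smallrna_mixtures[group]
        copies = group_copies.get(group, [])
        if not copies:
            continue
        lengths = sorted(mix)
        weights = np.array([mix[l] for l in lengths])
        weights = weights / weights.sum()
        hist: dict[int, int] = {}
        for _ in range(config.smallrna_reads_per_group):
            serial += 1
            name = f"{sample_id}:{serial:07d}"
            length = int(rng.choice(lengths, p=weights))
            copy = copies[int(rng.integers(len(copies)))]
            rel = int(rng.integers(0, copy.length - length))
            reverse = rng.random() < 0.5
            spec = spec_by_subfamily[copy.subfamily]
            copy_idx = int(copy.locus_id.rsplit("_", 1)[1])
            if copy_idx < spec.n_identical:
                family = ref.family_copies(copy.subfamily)
                targets = [
                    c
                    for c in family
                    if int(c.locus_id.rsplit("_", 1)[1]) < spec.n_identical
                ]
            else:
                targets = [copy]
            for t in targets:
                emit_single(
                    t.start + rel, length, reverse, len(targets), t is copy, name
                )
            hist[length] = hist.get(length, 0) + 1
            n_emitted_units += 1
        length_counts[group] = hist
    truth.smallrna_length_counts[sample_id] = length_counts

    # antisense gene reads at exact planted RPM
    L = config.smallrna_library_size
    free_by_gene = _gene_free_intervals(ref, min_len=40)
    antisense: dict[str, float] = {}
    for gene_idx, rpm in config.antisense_genes:
        gene = ref.genes[gene_idx]
        n_reads = int(round(rpm * L / 1e6))
        achieved = n_reads * 1e6 / L
        free = free_by_gene[gene_idx]
        if not free:
            raise ValueError(f"gene {gene.gene_id}: no repeat-free space")
        for _ in range(n_reads):
            serial += 1
            name = f"{sample_id}:{serial:07d}"
            s, e = free[int(rng.integers(len(free)))]
            pos = int(rng.integers(s, e - 22))
            emit_single(pos, 22, reverse=gene.strand == "+", nh=1, primary=True, name=name)
            n_emitted_units += 1
        antisense[gene.gene_id] = achieved
    truth.antisense_rpm[sample_id] = antisense

    # intergenic filler up to the exact planted library size
    features_end = max(
        [g.end for g in ref.genes] + [r.end for r in ref.repeats]
    )
    fill_start, fill_end = features_end + 200, len(ref.genome) - 200
    n_fill = L - n_emitted_units
    if n_fill < 0:
        raise ValueError("smallrna_library_size smaller than planted reads")
    if n_fill and fill_end - fill_start < 100:
        raise ValueError("no intergenic space for filler reads")
    positions = rng.integers(fill_start, fill_end - 35, size=n_fill)
    lengths = rng.integers(20, 31, size=n_fill)
    reverses = rng.random(n_fill) < 0.5
    for i in range(n_fill):
        serial += 1
        emit_single(
            int(positions[i]),
            int(lengths[i]),
            bool(reverses[i]),
            1,
            True,
            f"{sample_id}:{serial:07d}",
        )
    truth.library_sizes[sample_id] = L
    truth.total_units[sample_id] = L

    path = out_dir / f"{sample_id}.sam"
    _write_sam(segments, header_dict, path)
    return {sample_id: path}, truth


# ---------------------------------------------------------------------------
# deterministic coverage tiling


def simulate_locus_tiling(
    ref: ToyReference,
    locus: RepeatLocus,
    covered_segments: Sequence[tuple[int, int]],
    out_path: str | Path,
    read_len: int = 50,
    sample_id: str = "tiling",
) -> tuple[Path, dict[str, float]]:
    """Tile exact covered segments of a locus with perfect single-end reads.

    ``covered_segments`` are locus-relative half-open intervals; every base
    inside them (and no base outside) ends up covered, so the expected
    percent-covered and longest-run metrics are known by construction and
    returned alongside the SAM path.
    """
    header_dict = _sam_header(ref)
    header = pysam.AlignmentHeader.from_dict(header_dict)
    segments: list[pysam.AlignedSegment] = []
    serial = 0
    for a, b in covered_segments:
        if not 0 <= a < b <= locus.length:
            raise ValueError(f"segment ({a},{b}) outside locus of length {locus.length}")
        pos = a
        while pos < b:
            if b - pos >= read_len:
                start = min(pos, b - read_len)
                length = read_len
            else:
                start = max(a, b - read_len) if b - a >= read_len else a
                length = min(read_len, b - start)
            serial += 1
            abs_pos = locus.start + start
            seq = ref.genome[abs_pos : abs_pos + length]
            segments.append(
                _make_segment(
                    header,
                    f"{sample_id}:{serial:05d}",
                    0,
                    abs_pos,
                    f"{length}M",
                    seq,
                    1,
                    0,
                    0,
                )
            )
            pos = start + length
    out_path = Path(out_path)
    _write_sam(segments, header_dict, out_path)
    covered = sum(b - a for a, b in covered_segments)
    longest = _longest_merged_run(covered_segments)
    expected = {
        "pct_covered": 100.0 * covered / locus.length,
        "longest_run": float(longest),
        "n_reads": float(serial),
    }
    return out_path, expected


def _longest_merged_run(segments: Sequence[tuple[int, int]]) -> int:
    merged: list[list[int]] = []
    for a, b in sorted(segments):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return max((b - a) for a, b in merged) if merged else 0
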