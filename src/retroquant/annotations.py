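"""Repeat and gene annotation handling.

Repeat annotations (RepeatMasker-derived subfamilies) and gene annotations
(Ensembl-style GTF) are normalized to a single internal convention: 0-based,
half-open intervals, sorted by (chrom, start).  Subfamilies are aggregated
into analysis groups (L1, IAP, MaLR, ...) through a subfamily->group mapping
table; subfamilies absent from the table receive the sentinel group
``"unassigned"`` rather than raising, so user annotations with extra families
still run.

Gene masking removes every repeat locus that overlaps a gene body by at least
one base, on either strand.  This keeps repeat counts free of ordinary genic
transcription (a repeat inside an expressed intron would otherwise inherit
the host gene's signal).
"""

from __future__ import annotations

import csv
import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

UNASSIGNED = "unassigned"


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class RepeatLocus:
    """One annotated repeat insertion (0-based, half-open)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    group: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"locus {self.locus_id}: start {self.start} >= end {self.end}"
            )
        if not self.subfamily:
            raise AnnotationError(f"locus {self.locus_id}: empty subfamily")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneFeature:
    """One gene body (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


class GroupMap:
    """Total subfamily -> group lookup with an ``unassigned`` fallback."""

    def __init__(self, mapping: Mapping[str, str]):
        self._mapping = dict(mapping)

    def __getitem__(self, subfamily: str) -> str:
        return self._mapping.get(subfamily, UNASSIGNED)

    def __contains__(self, subfamily: str) -> bool:
        return subfamily in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupMap":
        """Read a two-column ``subfamily,group`` CSV (header required)."""
        path = Path(path)
        mapping: dict[str, str] = {}
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"subfamily", "group"} <= set(
                reader.fieldnames
            ):
                raise AnnotationError(
                    f"{path}: expected header with 'subfamily' and 'group' columns"
                )
            for row in reader:
                mapping[row["subfamily"]] = row["group"]
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subfamily", "group"])
            for sub, grp in sorted(self._mapping.items()):
                writer.writerow([sub, grp])


def _sorted_loci(loci: Iterable[RepeatLocus]) -> list[RepeatLocus]:
    return sorted(loci, key=lambda r: (r.chrom, r.start, r.end, r.locus_id))


def load_repeats(path: str | Path, dialect: str = "bed") -> list[RepeatLocus]:
    """Load repeat annotations as 0-based half-open loci.

    Parameters
    ----------
    path : file in BED6 (already half-open) or RepeatMasker ``.out``
        (1-based inclusive; start is shifted by -1 on import) format.
    dialect : {"bed", "repeatmasker_out"}
    """
    path = Path(path)
    if dialect == "bed":
        loci = _load_bed(path)
    elif dialect == "repeatmasker_out":
        loci = _load_rmsk_out(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _sorted_loci(loci)


def _load_bed(path: Path) -> list[RepeatLocus]:
    loci = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            strand = fields[5] if len(fields) > 5 else "+"
            if start >= end:
                raise AnnotationError(f"{path}:{lineno}: start >= end")
            loci.append(
                RepeatLocus(
                    locus_id=f"{name}|{chrom}:{start}-{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=name,
                )
            )
    return loci


def _load_rmsk_out(path: Path) -> list[RepeatLocus]:
    # RepeatMasker .out: 3 header lines, whitespace-separated columns
    # (score div del ins query begin end left strand repeat class/family ...).
    loci = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("SW", "score", "bit")):
                continue
            fields = stripped.split()
            if len(fields) < 10:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=10 RepeatMasker columns"
                )
            try:
                chrom = fields[4]
                start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                subfamily = fields[9]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise AnnotationError(f"{path}:{lineno}: start >= end after conversion")
            loci.append(
                RepeatLocus(
                    locus_id=f"{subfamily}|{chrom}:{start}-{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=subfamily,
                )
            )
    return loci


def write_bed(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    """Write loci as BED6 (normalized half-open coordinates)."""
    with Path(path).open("w") as fh:
        for loc in _sorted_loci(loci):
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.subfamily}\t0\t{loc.strand}\n"
            )


def load_genes(path: str | Path, biotypes: Sequence[str] | None = None) -> list[GeneFeature]:
    """Load gene bodies from a GTF; only feature type ``gene`` rows are kept.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    ``biotypes`` optionally restricts to the named biotypes (default: all).
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if "gene_id" not in feat.attributes:
            raise AnnotationError(f"{path}: gene row without gene_id attribute")
        gene_id = feat.attributes["gene_id"][0]
        bio = (
            feat.attributes.get("gene_biotype")
            or feat.attributes.get("gene_type")
            or ["unknown"]
        )[0]
        if biotypes is not None and bio not in biotypes:
            continue
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                biotype=bio,
            )
        )
    if not genes:
        warnings.warn(f"{path}: no 'gene' feature rows found", stacklevel=2)
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def assign_groups(
    repeats: Iterable[RepeatLocus], gmap: GroupMap
) -> list[RepeatLocus]:
    """Label each locus with its analysis group (or ``unassigned``)."""
    return [replace(loc, group=gmap[loc.subfamily]) for loc in repeats]


def mask_repeats_by_genes(
    repeats: Iterable[RepeatLocus], genes: Iterable[GeneFeature]
) -> tuple[list[RepeatLocus], list[RepeatLocus]]:
    """Partition repeats into (retained, dropped) by >=1 bp gene-body overlap.

    Overlap is strand-agnostic; ``retained + dropped`` is a partition of the
    input.  Half-open intervals that merely abut do not overlap.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        trees[gene.chrom].addi(gene.start, gene.end, gene.gene_id)
    retained, dropped = [], []
    for loc in repeats:
        if loc.chrom in trees and trees[loc.chrom].overlap(loc.start, loc.end):
            dropped.append(loc)
        else:
            retained.append(loc)
    return retained, dropped


def write_dropped_tsv(
    dropped: Iterable[RepeatLocus],
    genes: Iterable[GeneFeature],
    path: str | Path,
) -> None:
    """Write dropped loci with the gene_id(s) that triggered the mask."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        trees[gene.chrom].addi(gene.start, gene.end, gene.gene_id)
    with Path(path).open("w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tsubfamily\toverlapping_genes\n")
        for loc in _sorted_loci(dropped):
            hits = sorted(
                iv.data for iv in trees.get(loc.chrom, IntervalTree()).overlap(loc.start, loc.end)
            )
            fh.write(
                f"{loc.locus_id}\t{loc.chrom}\t{loc.start}\t{loc.end}\t"
                f"{loc.subfamily}\t{','.join(hits)}\n"
            )


class RepeatIndex:
    """Per-chromosome interval index over repeat loci.

    Supports the two queries the pipeline needs: loci overlapping a span by
    >=1 bp, and loci fully containing a span.
    """

    def __init__(self, loci: Iterable[RepeatLocus]):
        self.loci = _sorted_loci(loci)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for loc in self.loci:
            self._trees[loc.chrom].addi(loc.start, loc.end, loc)

    def __len__(self) -> int:
        return len(self.loci)

    def overlapping(self, chrom: str, start: int, end: int) -> list[RepeatLocus]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda r: (r.start, r.end, r.locus_id),
        )

    def containing(self, chrom: str, start: int, end: int) -> list[RepeatLocus]:
        return [
            loc
            for loc in self.overlapping(chrom, start, end)
            if loc.start <= start and end <= loc.end
        ]

    def units(self, level: str) -> list[str]:
        """All distinct subfamily or group labels in the index."""
        if level == "subfamily":
            vals = {loc.subfamily for loc in self.loci}
        elif level == "group":
            vals = {loc.group for loc in self.loci}
        else:
            raise ValueError(f"unknown level {level!r}")
        return sorted(vals)
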