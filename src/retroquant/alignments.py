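"""Alignment parsing and "perfectly mapping" read classification.

The counting pipeline keys on a strict notion of a perfect alignment:
zero mismatches according to the aligner's mismatch tag (STAR writes ``nM``,
samtools convention is ``NM``), and — under the default strict policy — no
insertions, deletions or soft-clipped bases either.  Splice skips (CIGAR
``N``) are tolerated by default because spliced aligners produce them for
genuinely perfect reads.

A countable "read unit" is one mate of one fragment, ``(read_id,
mate_index)``; a multimapper contributes several alignment records but one
unit.  Library size for RPM normalization is the number of distinct units
with at least one perfect alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam


class MissingMismatchTagError(ValueError):
    """No mismatch tag from the policy's priority list is present."""


class AlignmentParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one read (or mate) on the reference.

    ``blocks`` are the gapless aligned intervals (0-based half-open);
    consecutive blocks are separated by splice skips.  Deletions stay inside
    a block (they consume reference), and are reported via
    ``cigar_classes`` instead.
    """

    read_id: str
    mate_index: int  # 1/2 for paired mates, 0 for single-end
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    mismatch_tags: Mapping[str, int]
    cigar_classes: frozenset[str]
    is_primary: bool
    n_hits: int
    read_length: int

    @property
    def span(self) -> tuple[int, int]:
        """Outer reference span, first block start to last block end."""
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def unit(self) -> tuple[str, int]:
        return self.read_id, self.mate_index


@dataclass(frozen=True)
class PerfectPolicy:
    """What counts as a perfectly mapping alignment.

    ``tag_priority`` names the mismatch tags to consult in order; a record
    carrying none of them is a hard error (silent misclassification would
    corrupt every downstream count).  The strict default additionally
    rejects indels and soft-clips even at zero mismatches; the tag-only
    policy relies on the mismatch tag alone.
    """

    tag_priority: tuple[str, ...] = ("nM", "NM")
    forbid_indels: bool = True
    forbid_softclips: bool = True
    allow_splice_skip: bool = True

    def __post_init__(self) -> None:
        if not self.tag_priority:
            raise ValueError("tag_priority must be non-empty")

    @classmethod
    def strict(cls) -> "PerfectPolicy":
        return cls()

    @classmethod
    def tag_only(cls) -> "PerfectPolicy":
        return cls(forbid_indels=False, forbid_softclips=False)


@dataclass
class LibraryStats:
    """Library-size summary used for RPM/CPM scaling."""

    sample_id: str
    n_perfect_read_units: int
    n_total_read_units: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_perfect_read_units <= self.n_total_read_units:
            raise ValueError(
                "require 0 <= n_perfect_read_units <= n_total_read_units"
            )


_CIGAR_CLASS = {
    0: "match",  # M
    1: "insertion",  # I
    2: "deletion",  # D
    3: "skip",  # N
    4: "softclip",  # S
    5: "softclip",  # H: clipped bases, treated like soft-clips for policy
    7: "match",  # =
    8: "match",  # X
}


def blocks_from_cigar(
    cigartuples: Sequence[tuple[int, int]], pos: int
) -> tuple[tuple[tuple[int, int], ...], frozenset[str]]:
    """Aligned blocks and CIGAR operation classes for an alignment at pos.

    Blocks break only at splice skips (N); deletions extend the current
    block on the reference.
    """
    blocks: list[tuple[int, int]] = []
    classes: set[str] = set()
    cur = block_start = pos
    for op, length in cigartuples:
        cls = _CIGAR_CLASS.get(op)
        if cls is not None:
            classes.add(cls)
        if op in (0, 7, 8, 2):  # M/=/X/D consume reference
            cur += length
        elif op == 3:  # N: close the block
            if cur > block_start:
                blocks.append((block_start, cur))
            cur += length
            block_start = cur
    if cur > block_start:
        blocks.append((block_start, cur))
    if not blocks:
        raise AlignmentParseError("alignment with no reference-consuming CIGAR ops")
    return tuple(blocks), frozenset(classes)


class AlignmentStream:
    """Iterable of AlignmentRecord from a SAM/BAM file.

    Unmapped records are skipped and tallied on ``n_unmapped_skipped``;
    secondary alignments are retained (the deduplication logic downstream
    needs them).  Iteration order follows the file and is deterministic.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.n_unmapped_skipped = 0

    def __iter__(self) -> Iterator[AlignmentRecord]:
        self.n_unmapped_skipped = 0
        with pysam.AlignmentFile(str(self.path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    self.n_unmapped_skipped += 1
                    continue
                yield _convert(rec)


def _convert(rec: pysam.AlignedSegment) -> AlignmentRecord:
    if rec.cigartuples is None:
        raise AlignmentParseError(f"mapped record {rec.query_name} without CIGAR")
    blocks, classes = blocks_from_cigar(rec.cigartuples, rec.reference_start)
    tags = {}
    for tag in ("nM", "NM"):
        if rec.has_tag(tag):
            tags[tag] = int(rec.get_tag(tag))
    if rec.is_paired:
        mate = 1 if rec.is_read1 else 2
    else:
        mate = 0
    read_length = rec.query_length or rec.infer_read_length() or 0
    if read_length < 1:
        raise AlignmentParseError(f"record {rec.query_name}: cannot infer read length")
    return AlignmentRecord(
        read_id=rec.query_name,
        mate_index=mate,
        chrom=rec.reference_name,
        blocks=blocks,
        strand="-" if rec.is_reverse else "+",
        mismatch_tags=tags,
        cigar_classes=classes,
        is_primary=not rec.is_secondary,
        n_hits=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
        read_length=read_length,
    )


def parse_alignments(path: str | Path) -> AlignmentStream:
    """Open a SAM/BAM file as a re-iterable stream of AlignmentRecord."""
    return AlignmentStream(path)


def resolve_mismatches(
    rec: AlignmentRecord, tag_priority: Sequence[str] = ("nM", "NM")
) -> int:
    """Mismatch count from the first available tag in priority order."""
    for tag in tag_priority:
        if tag in rec.mismatch_tags:
            return rec.mismatch_tags[tag]
    raise MissingMismatchTagError(
        f"read {rec.read_id}: none of the mismatch tags "
        f"{tuple(tag_priority)} present"
    )


def is_perfect(rec: AlignmentRecord, policy: PerfectPolicy | None = None) -> bool:
    """Classify one alignment under the perfect-mapping policy."""
    policy = policy or PerfectPolicy()
    if resolve_mismatches(rec, policy.tag_priority) != 0:
        return False
    if policy.forbid_indels and (
        "insertion" in rec.cigar_classes or "deletion" in rec.cigar_classes
    ):
        return False
    if policy.forbid_softclips and "softclip" in rec.cigar_classes:
        return False
    if not policy.allow_splice_skip and "skip" in rec.cigar_classes:
        return False
    return True


def library_size_perfect(
    alignments: Iterable[AlignmentRecord],
    policy: PerfectPolicy | None = None,
    sample_id: str = "sample",
) -> LibraryStats:
    """Count distinct read units, total and with >=1 perfect alignment.

    A multimapping read is counted once however many alignment records it
    carries.
    """
    policy = policy or PerfectPolicy()
    perfect: set[tuple[str, int]] = set()
    total: set[tuple[str, int]] = set()
    for rec in alignments:
        total.add(rec.unit)
        if rec.unit not in perfect and is_perfect(rec, policy):
            perfect.add(rec.unit)
    return LibraryStats(
        sample_id=sample_id,
        n_perfect_read_units=len(perfect),
        n_total_read_units=len(total),
    )


def write_library_stats(stats: Iterable[LibraryStats], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tn_perfect_read_units\tn_total_read_units\n")
        for st in stats:
            fh.write(
                f"{st.sample_id}\t{st.n_perfect_read_units}\t{st.n_total_read_units}\n"
            )
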