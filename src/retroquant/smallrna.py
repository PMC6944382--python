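"""Small-RNA length spectra per repeat group and the siRNA-target filter.

Small-RNA populations separate by length: Dicer-dependent siRNAs peak at
21-23 nt while PIWI-bound piRNAs peak at 25-30 nt, so the read-length
histogram of a repeat group reveals which silencing pathway engages it.
Histograms are computed on primary alignments only (one record per read),
attributed to a group by >=1 bp overlap with any locus of that group, and
scaled to RPM.

The siRNA-target candidate filter flags genes with antisense endogenous
21-23 nt small RNAs above a mean abundance threshold (strictly > 50 RPM
averaged over libraries by default).  Identifying the dsRNA origin of such
siRNAs is a curation step outside this filter; calls carry
``origin_identified="unknown"``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .alignments import (
    AlignmentRecord,
    LibraryStats,
    PerfectPolicy,
    is_perfect,
    resolve_mismatches,
)
from .annotations import GeneFeature, RepeatIndex


@dataclass
class LengthSpectrum:
    """Per-group read-length histogram (raw counts and RPM)."""

    sample_id: str
    counts: dict[str, dict[int, int]]
    rpm: dict[str, dict[int, float]]
    min_len: int = 18
    max_len: int = 32
    n_out_of_range: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sample, group, length, count, rpm)."""
        rows = []
        for group in sorted(self.counts):
            for length in range(self.min_len, self.max_len + 1):
                rows.append(
                    {
                        "sample": self.sample_id,
                        "group": group,
                        "length": length,
                        "count": self.counts[group].get(length, 0),
                        "rpm": self.rpm[group].get(length, 0.0),
                    }
                )
        return pd.DataFrame(rows)

    def modal_length(self, group: str) -> int:
        hist = self.counts.get(group, {})
        if not hist:
            raise KeyError(f"no reads attributed to group {group!r}")
        return max(sorted(hist), key=lambda l: hist[l])


@dataclass
class SirnaTargetCall:
    gene_id: str
    antisense_rpm_21_23: float
    passes: bool
    origin_identified: str = "unknown"


def length_histogram(
    alignments: Iterable[AlignmentRecord],
    repeats: RepeatIndex,
    library: LibraryStats,
    min_len: int = 18,
    max_len: int = 32,
    max_mismatches: int = 1,
    tag_priority: Sequence[str] = ("nM", "NM"),
    sample_id: str | None = None,
) -> LengthSpectrum:
    """Read-length histogram of primary alignments per repeat group.

    An alignment is attributed to every group whose loci it overlaps by
    >=1 bp (attribution, not containment: small RNAs are much shorter than
    the elements).  Reads outside ``[min_len, max_len]`` are tallied on
    ``n_out_of_range`` rather than silently dropped.  ``max_mismatches``
    mirrors the small-RNA mapping tolerance (1 mismatch by default).
    """
    if library.n_perfect_read_units <= 0:
        raise ValueError("library with zero perfect read units")
    counts: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    out_of_range = 0
    for rec in alignments:
        if not rec.is_primary:
            continue
        if resolve_mismatches(rec, tag_priority) > max_mismatches:
            continue
        groups = set()
        for s, e in rec.blocks:
            for loc in repeats.overlapping(rec.chrom, s, e):
                groups.add(loc.group)
        if not groups:
            continue
        if not min_len <= rec.read_length <= max_len:
            out_of_range += 1
            continue
        for group in groups:
            counts[group][rec.read_length] += 1
    scale = 1e6 / library.n_perfect_read_units
    rpm = {
        g: {l: c * scale for l, c in hist.items()} for g, hist in counts.items()
    }
    return LengthSpectrum(
        sample_id=sample_id or library.sample_id,
        counts={g: dict(h) for g, h in counts.items()},
        rpm=rpm,
        min_len=min_len,
        max_len=max_len,
        n_out_of_range=out_of_range,
    )


def sirna_target_candidates(
    genes: Iterable[GeneFeature],
    samples: Sequence[tuple[Iterable[AlignmentRecord], LibraryStats]],
    min_rpm: float = 50.0,
    len_range: tuple[int, int] = (21, 23),
    policy: PerfectPolicy | None = None,
) -> list[SirnaTargetCall]:
    """Flag genes with antisense 21-23 nt small RNAs above a mean RPM cutoff.

    For each supplied library, primary perfect alignments with read length
    inside ``len_range`` that overlap a gene body on the opposite strand
    are counted and scaled to RPM; per-gene RPM values are then averaged
    over the libraries.  A gene passes iff the average is strictly greater
    than ``min_rpm``.
    """
    if not samples:
        raise ValueError("need at least one (alignments, library) pair")
    policy = policy or PerfectPolicy()
    genes = list(genes)
    for gene in genes:
        if gene.strand not in "+-":
            raise ValueError(f"gene {gene.gene_id} without strand")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        trees[gene.chrom].addi(gene.start, gene.end, gene)
    lo, hi = len_range
    per_gene_rpm: dict[str, list[float]] = {g.gene_id: [] for g in genes}
    for stream, library in samples:
        if library.n_perfect_read_units <= 0:
            raise ValueError(f"library {library.sample_id}: zero perfect units")
        counts: dict[str, int] = defaultdict(int)
        for rec in stream:
            if not rec.is_primary:
                continue
            if not lo <= rec.read_length <= hi:
                continue
            if not is_perfect(rec, policy):
                continue
            hit_ids = set()
            for s, e in rec.blocks:
                if rec.chrom not in trees:
                    continue
                for iv in trees[rec.chrom].overlap(s, e):
                    gene = iv.data
                    if gene.strand != rec.strand:
                        hit_ids.add(gene.gene_id)
            for gid in hit_ids:
                counts[gid] += 1
        scale = 1e6 / library.n_perfect_read_units
        for gene in genes:
            per_gene_rpm[gene.gene_id].append(counts.get(gene.gene_id, 0) * scale)
    calls = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        values = per_gene_rpm[gene.gene_id]
        avg = sum(values) / len(values)
        calls.append(
            SirnaTargetCall(
                gene_id=gene.gene_id,
                antisense_rpm_21_23=avg,
                passes=avg > min_rpm,
            )
        )
    return calls


def write_spectrum_tsv(
    spectrum: LengthSpectrum, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        spectrum.to_frame().to_csv(fh, sep="\t", index=False)
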