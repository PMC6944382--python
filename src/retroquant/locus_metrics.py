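"""Per-locus coverage metrics for full-length LINE-1 elements.

Whether an individual genomic L1 insertion is genuinely transcribed cannot
be decided from read counts alone: multimapping reads from other copies
pile onto intact elements.  Locus-level coverage of perfect alignments
(with multimappers retained) is more informative — a bona fide source
locus shows contiguous coverage across the element and often read-through
into its unique genomic flanks.

This module computes, per locus: the per-base depth profile, the percent
of positions covered at >= ``min_depth``, the longest contiguous covered
run, the number of distinct perfect read units touching the locus, and the
covered bases immediately contiguous with each element edge inside a flank
window.  Candidate expressed elements are ranked by a deterministic
composite key (coverage first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .alignments import AlignmentRecord, LibraryStats, PerfectPolicy, is_perfect
from .annotations import RepeatLocus


@dataclass
class LocusCoverage:
    """Coverage profile and summary metrics for one locus."""

    locus_id: str
    chrom: str
    start: int
    length: int
    depth: np.ndarray  # per-base depth over [start, start+length)
    pct_covered: float
    longest_run: int
    reads_in_locus: int
    flank_5p_readthrough_bp: int
    flank_3p_readthrough_bp: int
    min_depth: int = 1
    flank_bp: int = 500


class CandidateEntry(NamedTuple):
    locus_id: str
    reads_in_locus: int
    pct_covered: float
    longest_run: int


@dataclass
class CandidateRanking:
    """Loci ordered by (pct_covered, reads_in_locus, longest_run) desc."""

    entries: list[CandidateEntry]


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        if cur > best:
            best = cur
    return best


def compute_locus_coverage(
    alignments: Iterable[AlignmentRecord],
    locus: RepeatLocus,
    policy: PerfectPolicy | None = None,
    min_depth: int = 1,
    flank_bp: int = 500,
) -> LocusCoverage:
    """Depth profile and metrics from perfect alignments over one locus.

    Every perfect alignment — primary or secondary — contributes its aligned
    blocks; paired mates contribute independently (no insert imputation).
    Flank read-through is the run of covered bases contiguous with the
    element edge, measured over ``[start-flank_bp, start)`` (5') and
    ``[end, end+flank_bp)`` (3') in genomic orientation.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    policy = policy or PerfectPolicy()
    length = locus.length
    win_start = locus.start - flank_bp
    win_len = length + 2 * flank_bp
    depth = np.zeros(win_len, dtype=np.int64)
    units: set[tuple[str, int]] = set()
    for rec in alignments:
        if rec.chrom != locus.chrom:
            continue
        if not is_perfect(rec, policy):
            continue
        touches = False
        for s, e in rec.blocks:
            a, b = max(s, win_start), min(e, win_start + win_len)
            if a < b:
                depth[a - win_start : b - win_start] += 1
            if max(s, locus.start) < min(e, locus.end):
                touches = True
        if touches:
            units.add(rec.unit)
    inner = depth[flank_bp : flank_bp + length]
    covered = inner >= min_depth
    n_cov = int(covered.sum())
    # contiguous covered run walking outward from each element edge
    flank5 = 0
    for i in range(flank_bp - 1, -1, -1):
        if depth[i] >= min_depth:
            flank5 += 1
        else:
            break
    flank3 = 0
    for i in range(flank_bp + length, win_len):
        if depth[i] >= min_depth:
            flank3 += 1
        else:
            break
    return LocusCoverage(
        locus_id=locus.locus_id,
        chrom=locus.chrom,
        start=locus.start,
        length=length,
        depth=inner.copy(),
        pct_covered=100.0 * n_cov / length,
        longest_run=_longest_true_run(covered),
        reads_in_locus=len(units),
        flank_5p_readthrough_bp=flank5,
        flank_3p_readthrough_bp=flank3,
        min_depth=min_depth,
        flank_bp=flank_bp,
    )


def rank_candidates(coverages: Sequence[LocusCoverage]) -> CandidateRanking:
    """Deterministic total order over candidate expressed loci.

    Sort key: pct_covered desc, reads_in_locus desc, longest_run desc,
    locus_id asc.
    """
    if not coverages:
        raise ValueError("no coverages to rank")
    entries = [
        CandidateEntry(c.locus_id, c.reads_in_locus, c.pct_covered, c.longest_run)
        for c in coverages
    ]
    entries.sort(
        key=lambda e: (-e.pct_covered, -e.reads_in_locus, -e.longest_run, e.locus_id)
    )
    return CandidateRanking(entries)


def export_bedgraph(
    cov: LocusCoverage,
    scale: str = "raw",
    library: LibraryStats | None = None,
) -> list[str]:
    """Run-length-encode the depth profile as bedGraph lines.

    Zero-depth runs are omitted.  With ``scale="cpm"`` each depth value is
    scaled by 1e6 over the library's perfect read units so tracks from
    different libraries are directly comparable.
    """
    if scale not in ("raw", "cpm"):
        raise ValueError(f"unknown scale {scale!r}")
    factor = 1.0
    if scale == "cpm":
        if library is None or library.n_perfect_read_units <= 0:
            raise ValueError("cpm scaling requires a library with >0 perfect units")
        factor = 1e6 / library.n_perfect_read_units
    lines: list[str] = []
    depth = cov.depth
    i = 0
    n = len(depth)
    while i < n:
        j = i
        while j < n and depth[j] == depth[i]:
            j += 1
        if depth[i] > 0:
            value = depth[i] * factor
            val_str = f"{int(value)}" if scale == "raw" else f"{value:.6g}"
            lines.append(f"{cov.chrom}\t{cov.start + i}\t{cov.start + j}\t{val_str}")
        i = j
    return lines


def write_metrics_tsv(
    coverages: Sequence[LocusCoverage],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "locus_id\tchrom\tstart\tlength\treads_in_locus\tpct_covered\t"
            "longest_run\tflank_5p_readthrough_bp\tflank_3p_readthrough_bp\n"
        )
        for c in coverages:
            fh.write(
                f"{c.locus_id}\t{c.chrom}\t{c.start}\t{c.length}\t"
                f"{c.reads_in_locus}\t{c.pct_covered:.4g}\t{c.longest_run}\t"
                f"{c.flank_5p_readthrough_bp}\t{c.flank_3p_readthrough_bp}\n"
            )


def load_locus_list(path: str | Path) -> list[RepeatLocus]:
    """Read a locus list as BED or a full-length-L1-style CSV.

    The CSV dialect expects a header containing at least
    ``locus_id,chrom,start,end`` (optionally ``strand`` and ``subfamily``),
    with 0-based half-open coordinates.
    """
    import csv

    from .annotations import load_repeats

    path = Path(path)
    if path.suffix.lower() in (".bed",):
        return load_repeats(path, dialect="bed")
    loci = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"locus_id", "chrom", "start", "end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: locus CSV needs columns {sorted(required)}")
        for row in reader:
            loci.append(
                RepeatLocus(
                    locus_id=row["locus_id"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand", "+") or "+",
                    subfamily=row.get("subfamily", "L1") or "L1",
                )
            )
    return loci
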