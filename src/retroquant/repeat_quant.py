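"""Subfamily/group-level repeat counting and RPM/RPKM normalization.

The counting algorithm applies four restrictions:

1. only perfectly mapping alignments are considered (see
   :mod:`retroquant.alignments`);
2. an alignment counts only if it is completely contained in a repeat locus
   (every aligned base, and by default the splice gaps too, inside
   ``[locus.start, locus.end)``);
3. repeat loci overlapping gene bodies must have been removed upstream
   (:func:`retroquant.annotations.mask_repeats_by_genes`);
4. a read unit aligning to several genomic copies of the same subfamily is
   counted once for that subfamily.

Restriction 4 is implemented with set semantics over distinct
``(read_unit, unit_label)`` pairs, so secondary alignments participate but
never inflate a count, and the result is invariant to input order and to
duplicated records.  At group level the deduplication key is
``(read_unit, group)`` — the natural lift of the subfamily rule — so a unit
hitting two subfamilies of one group counts once for the group.

RPM divides raw counts by the number of perfectly mapping read units in
millions; RPKM additionally divides by the total retained annotated length
of the unit in kilobases.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentRecord, LibraryStats, PerfectPolicy, is_perfect
from .annotations import RepeatIndex, RepeatLocus

COUNT_COLUMNS = ["raw_count", "rpm", "rpkm"]


@dataclass
class CountTable:
    """Per-unit raw counts and normalized values for one sample.

    ``counts`` is indexed by unit (subfamily or group name) with columns
    ``raw_count``, ``rpm`` and ``rpkm`` (NaN until the corresponding
    normalization has been applied).
    """

    sample_id: str
    unit_level: str
    counts: pd.DataFrame
    library_size: int | None = None

    def copy(self) -> "CountTable":
        return CountTable(
            self.sample_id, self.unit_level, self.counts.copy(), self.library_size
        )

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with Path(path).open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df = self.counts.copy()
            df.insert(0, "unit", df.index)
            df["library_size"] = self.library_size
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str, unit_level: str) -> "CountTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        lib = None
        if "library_size" in df.columns and df["library_size"].notna().any():
            lib = int(df["library_size"].iloc[0])
        counts = df.set_index("unit")[COUNT_COLUMNS]
        return cls(sample_id, unit_level, counts, lib)


@dataclass
class AggregateTable:
    """Mean RPM per unit over replicates of one condition."""

    unit_level: str
    mean_rpm: pd.Series
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def count_repeats(
    alignments: Iterable[AlignmentRecord],
    retained_repeats: RepeatIndex | Iterable[RepeatLocus],
    policy: PerfectPolicy | None = None,
    level: str = "subfamily",
    require_gap_containment: bool = True,
) -> CountTable:
    """Count deduplicated perfect read units fully contained in repeat loci.

    ``retained_repeats`` must already be gene-masked.  With
    ``require_gap_containment`` (the default) the whole outer span of a
    spliced alignment must lie inside the locus; otherwise each aligned
    block is checked individually and splice gaps may bridge outside.
    """
    policy = policy or PerfectPolicy()
    index = (
        retained_repeats
        if isinstance(retained_repeats, RepeatIndex)
        else RepeatIndex(retained_repeats)
    )
    if len(index) == 0:
        warnings.warn("empty repeat annotation: all counts zero", stacklevel=2)
    units = index.units(level)
    seen: set[tuple[str, int, str]] = set()
    sample_id = "sample"
    for rec in alignments:
        if not is_perfect(rec, policy):
            continue
        span_start, span_end = rec.span
        if require_gap_containment:
            hits = index.containing(rec.chrom, span_start, span_end)
        else:
            hits = [
                loc
                for loc in index.overlapping(rec.chrom, span_start, span_end)
                if all(loc.start <= s and e <= loc.end for s, e in rec.blocks)
            ]
        for loc in hits:
            label = loc.subfamily if level == "subfamily" else loc.group
            seen.add((rec.read_id, rec.mate_index, label))
    raw = defaultdict(int)
    for _, _, label in seen:
        raw[label] += 1
    counts = pd.DataFrame(
        {
            "raw_count": [raw.get(u, 0) for u in units],
            "rpm": np.nan,
            "rpkm": np.nan,
        },
        index=pd.Index(units, name="unit"),
    )
    return CountTable(sample_id=sample_id, unit_level=level, counts=counts)


def normalize_rpm(table: CountTable, stats: LibraryStats) -> CountTable:
    """RPM = raw_count * 1e6 / perfect read units in the library."""
    if stats.n_perfect_read_units <= 0:
        raise ValueError(
            f"sample {stats.sample_id}: zero perfect read units, cannot compute RPM"
        )
    out = table.copy()
    out.sample_id = stats.sample_id
    out.library_size = stats.n_perfect_read_units
    out.counts["rpm"] = (
        out.counts["raw_count"] * 1e6 / stats.n_perfect_read_units
    )
    return out


def unit_annotated_lengths(
    retained_repeats: Iterable[RepeatLocus], level: str
) -> dict[str, int]:
    """Total retained annotated length (bp) per subfamily or group."""
    lengths: dict[str, int] = defaultdict(int)
    for loc in retained_repeats:
        label = loc.subfamily if level == "subfamily" else loc.group
        lengths[label] += loc.length
    return dict(lengths)


def normalize_rpkm(
    table: CountTable, retained_repeats: Iterable[RepeatLocus] | RepeatIndex
) -> CountTable:
    """RPKM = RPM / (total retained annotated length of the unit in kb)."""
    if table.counts["rpm"].isna().any():
        raise ValueError("RPM must be computed before RPKM")
    loci = (
        retained_repeats.loci
        if isinstance(retained_repeats, RepeatIndex)
        else list(retained_repeats)
    )
    lengths = unit_annotated_lengths(loci, table.unit_level)
    out = table.copy()
    kb = []
    for unit in out.counts.index:
        if lengths.get(unit, 0) <= 0:
            raise ValueError(f"unit {unit}: zero annotated length, cannot compute RPKM")
        kb.append(lengths[unit] / 1000.0)
    out.counts["rpkm"] = out.counts["rpm"] / np.asarray(kb)
    return out


def mean_over_replicates(tables: Sequence[CountTable]) -> AggregateTable:
    """Arithmetic mean RPM per unit; units absent from a replicate count as 0."""
    if not tables:
        raise ValueError("need at least one replicate")
    levels = {t.unit_level for t in tables}
    if len(levels) != 1:
        raise ValueError(f"replicates mix unit levels: {sorted(levels)}")
    all_units = sorted(set().union(*(t.counts.index for t in tables)))
    mat = pd.DataFrame(
        {
            i: t.counts["rpm"].reindex(all_units, fill_value=0.0)
            for i, t in enumerate(tables)
        }
    )
    if mat.isna().any().any():
        raise ValueError("RPM missing in a replicate; run normalize_rpm first")
    return AggregateTable(
        unit_level=levels.pop(),
        mean_rpm=mat.mean(axis=1),
        n_replicates=len(tables),
    )


def write_aggregate_tsv(
    agg: AggregateTable, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("unit\tmean_rpm\tn_replicates\n")
        for unit, value in agg.mean_rpm.items():
            fh.write(f"{unit}\t{value:.6g}\t{agg.n_replicates}\n")
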