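"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the production code paths: perfect-read
classification is re-derived from the raw tags and CIGAR classes, overlap
and containment are checked by exhaustive all-pairs scans, and
deduplication materializes every (read unit, locus) containment pair in a
set before counting.
"""

from __future__ import annotations

from collections import defaultdict


def oracle_is_perfect(rec, forbid_indels=True, forbid_softclips=True):
    mm = rec.mismatch_tags.get("nM", rec.mismatch_tags.get("NM"))
    if mm is None:
        raise ValueError(f"{rec.read_id}: no mismatch tag")
    if mm != 0:
        return False
    if forbid_indels and ({"insertion", "deletion"} & rec.cigar_classes):
        return False
    if forbid_softclips and "softclip" in rec.cigar_classes:
        return False
    return True


def oracle_count(records, retained_loci, level="subfamily"):
    """All-pairs containment enumeration with set deduplication."""
    pairs = set()
    for rec in records:
        if not oracle_is_perfect(rec):
            continue
        span_start = rec.blocks[0][0]
        span_end = rec.blocks[-1][1]
        for locus in retained_loci:
            if locus.chrom != rec.chrom:
                continue
            if locus.start <= span_start and span_end <= locus.end:
                label = locus.subfamily if level == "subfamily" else locus.group
                pairs.add((rec.read_id, rec.mate_index, label))
    counts = defaultdict(int)
    for _, _, label in pairs:
        counts[label] += 1
    return dict(counts)


def oracle_mask(repeats, genes):
    """All-pairs >=1 bp overlap scan; returns (retained, dropped) sets."""
    retained, dropped = [], []
    for rep in repeats:
        hit = any(
            g.chrom == rep.chrom and max(g.start, rep.start) < min(g.end, rep.end)
            for g in genes
        )
        (dropped if hit else retained).append(rep)
    return retained, dropped


def oracle_rank_key(entry):
    return (-entry.pct_covered, -entry.reads_in_locus, -entry.longest_run,
            entry.locus_id)
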