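import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from retroquant.alignments import AlignmentRecord
from retroquant.annotations import GeneFeature, RepeatLocus


def make_rec(
    read_id="r1",
    mate=0,
    chrom="chr1",
    blocks=((100, 175),),
    strand="+",
    nm=0,
    classes=("match",),
    primary=True,
    nh=1,
    read_length=None,
    tags=None,
):
    """Hand-construct an AlignmentRecord for unit tests."""
    blocks = tuple(tuple(b) for b in blocks)
    if read_length is None:
        read_length = sum(e - s for s, e in blocks)
    if tags is None:
        tags = {"nM": nm, "NM": nm}
    return AlignmentRecord(
        read_id=read_id,
        mate_index=mate,
        chrom=chrom,
        blocks=blocks,
        strand=strand,
        mismatch_tags=tags,
        cigar_classes=frozenset(classes),
        is_primary=primary,
        n_hits=nh,
        read_length=read_length,
    )


def make_locus(locus_id, start, end, subfamily="L1Md_T", group="L1",
               chrom="chr1", strand="+"):
    return RepeatLocus(
        locus_id=locus_id, chrom=chrom, start=start, end=end,
        strand=strand, subfamily=subfamily, group=group,
    )


def make_gene(gene_id, start, end, strand="+", chrom="chr1",
              biotype="protein_coding"):
    return GeneFeature(
        gene_id=gene_id, chrom=chrom, start=start, end=end,
        strand=strand, biotype=biotype,
    )


@pytest.fixture(scope="session")
def toy_reference():
    """Small default toy reference shared across tests."""
    from retroquant.synthetic import SyntheticConfig, build_toy_reference

    config = SyntheticConfig(seed=11, replicates=1, total_fragments=None, background_reads=300)
    return config, build_toy_reference(config)


@pytest.fixture(scope="session")
def simulated_dataset(toy_reference, tmp_path_factory):
    """One simulated mRNA dataset (SAM paths + truth) for reuse."""
    from retroquant.synthetic import simulate_alignments

    config, ref = toy_reference
    out = tmp_path_factory.mktemp("sim")
    sam_paths, truth = simulate_alignments(config, ref, out)
    return config, ref, sam_paths, truth
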