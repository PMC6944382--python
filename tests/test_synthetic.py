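"""Simulator construction rules, determinism and truth-table closure."""

import hashlib

import numpy as np
import pytest

from retroquant.alignments import (
    PerfectPolicy,
    library_size_perfect,
    parse_alignments,
)
from retroquant.annotations import RepeatIndex, mask_repeats_by_genes
from retroquant.repeat_quant import count_repeats
from retroquant.synthetic import (
    SubfamilySpec,
    SyntheticConfig,
    SyntheticTruth,
    build_toy_reference,
    simulate_alignments,
    simulate_locus_tiling,
    simulate_smallrna,
    write_reference,
)


def _md5(path):
    return hashlib.md5(path.read_bytes()).hexdigest()


class TestReference:
    def test_identical_copies_share_sequence(self, toy_reference):
        config, ref = toy_reference
        for spec in config.subfamily_specs:
            copies = ref.family_copies(spec.subfamily)
            master = copies[0]
            master_seq = ref.genome[master.start : master.end]
            for copy in copies:
                idx = int(copy.locus_id.rsplit("_", 1)[1])
                seq = ref.genome[copy.start : copy.end]
                if idx < spec.n_identical:
                    if idx > 0:
                        ident = next(
                            c for c in copies
                            if int(c.locus_id.rsplit("_", 1)[1]) == 0
                        )
                        assert seq == ref.genome[ident.start : ident.end]

    def test_identical_copy_count_explicit(self):
        config = SyntheticConfig(
            seed=2,
            subfamily_specs=(
                SubfamilySpec("L1Md_T", "L1", n_copies=3, copy_length=1000,
                              n_identical=2),
            ),
            n_genes=2,
            fraction_repeats_in_genes=0.0,
        )
        ref = build_toy_reference(config)
        seqs = [ref.genome[c.start : c.end] for c in ref.repeats]
        assert seqs[0] == seqs[1] if ref.repeats[0].locus_id.endswith("0") else True
        identical = [s for s in seqs if seqs.count(s) >= 2]
        assert len(identical) == 2

    def test_embedded_fraction_exact(self):
        config = SyntheticConfig(
            seed=3,
            subfamily_specs=(
                SubfamilySpec("A", "GA", n_copies=5, copy_length=300),
                SubfamilySpec("B", "GB", n_copies=5, copy_length=300),
            ),
            n_genes=6,
            fraction_repeats_in_genes=0.5,
        )
        ref = build_toy_reference(config)
        retained, dropped = mask_repeats_by_genes(ref.repeats, ref.genes)
        assert len(dropped) == 5
        assert {r.locus_id for r in dropped} == set(ref.in_gene_locus_ids)

    def test_placement_overflow_errors(self):
        config = SyntheticConfig(seed=0, genome_length=10_000)
        with pytest.raises(ValueError, match="genome_length"):
            build_toy_reference(config)

    def test_reference_deterministic_and_files_written(self, tmp_path):
        config = SyntheticConfig(seed=5)
        ref1 = build_toy_reference(config)
        ref2 = build_toy_reference(config)
        assert ref1.genome == ref2.genome
        paths = write_reference(ref1, tmp_path)
        for key in ("fasta", "repeats_bed", "genes_gtf", "groups_csv", "l1_csv"):
            assert paths[key].exists() and paths[key].stat().st_size > 0


class TestSimulateAlignments:
    def test_multimappers_have_nh_and_single_primary(self, simulated_dataset):
        _, _, sam_paths, _ = simulated_dataset
        path = next(iter(sam_paths.values()))
        by_unit = {}
        for rec in parse_alignments(path):
            by_unit.setdefault(rec.unit, []).append(rec)
        multi = [v for v in by_unit.values() if len(v) > 1]
        assert multi, "expected multimapping read units from identical copies"
        for recs in multi:
            assert sum(r.is_primary for r in recs) == 1
            assert all(r.n_hits == len(recs) for r in recs)

    def test_same_seed_byte_identical(self, toy_reference, tmp_path):
        config, ref = toy_reference
        p1, _ = simulate_alignments(config, ref, tmp_path / "a")
        p2, _ = simulate_alignments(config, ref, tmp_path / "b")
        for sample in p1:
            assert _md5(p1[sample]) == _md5(p2[sample])

    def test_mismatch_and_indel_reads_present_and_tagged(self, simulated_dataset):
        _, _, sam_paths, _ = simulated_dataset
        path = next(iter(sam_paths.values()))
        n_mismatch = n_indel = 0
        for rec in parse_alignments(path):
            if rec.mismatch_tags["nM"] == 1:
                n_mismatch += 1
            if {"insertion", "deletion"} & rec.cigar_classes:
                n_indel += 1
                assert rec.mismatch_tags["nM"] == 0
                assert rec.mismatch_tags["NM"] == 2
        assert n_mismatch > 0 and n_indel > 0

    def test_truth_closure_counts_and_library(self, simulated_dataset):
        config, ref, sam_paths, truth = simulated_dataset
        retained, _ = mask_repeats_by_genes(ref.repeats, ref.genes)
        index = RepeatIndex(retained)
        policy = PerfectPolicy()
        for sample, path in sam_paths.items():
            records = list(parse_alignments(path))
            stats = library_size_perfect(records, policy, sample)
            assert stats.n_perfect_read_units == truth.library_sizes[sample]
            table = count_repeats(records, index, policy)
            for subfamily, expected in truth.subfamily_counts[sample].items():
                assert table.counts.loc[subfamily, "raw_count"] == expected

    def test_planted_fold_change_bookkeeping(self, simulated_dataset):
        config, _, _, truth = simulated_dataset
        assert truth.fold_changes["double_mutant"]["L1Md_T"] == pytest.approx(6.0)
        assert truth.fold_changes["control"]["L1Md_T"] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def smallrna(tmp_path_factory, toy_reference):
    config, _ = toy_reference
    small = SyntheticConfig(
        seed=config.seed,
        smallrna_library_size=20_000,
        smallrna_reads_per_group=300,
        antisense_genes=((0, 100.0), (1, 50.0)),
    )
    ref_small = build_toy_reference(small)
    out = tmp_path_factory.mktemp("srna")
    paths, truth = simulate_smallrna(small, ref_small, out)
    return small, ref_small, paths, truth


class TestSimulateSmallRNA:
    def test_library_size_exact(self, smallrna):
        _, _, paths, truth = smallrna
        sample, path = next(iter(paths.items()))
        stats = library_size_perfect(parse_alignments(path), sample_id=sample)
        assert stats.n_perfect_read_units == truth.library_sizes[sample] == 20_000

    def test_planted_lengths_match_truth(self, smallrna):
        from retroquant.smallrna import length_histogram

        config, ref, paths, truth = smallrna
        sample, path = next(iter(paths.items()))
        records = list(parse_alignments(path))
        stats = library_size_perfect(records, sample_id=sample)
        spec = length_histogram(records, RepeatIndex(ref.repeats), stats)
        for group, hist in truth.smallrna_length_counts[sample].items():
            assert spec.counts[group] == hist

    def test_planted_antisense_rpm_recovered(self, smallrna):
        from retroquant.smallrna import sirna_target_candidates

        config, ref, paths, truth = smallrna
        sample, path = next(iter(paths.items()))
        records = list(parse_alignments(path))
        stats = library_size_perfect(records, sample_id=sample)
        calls = sirna_target_candidates(ref.genes, [(records, stats)])
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["gene0"].antisense_rpm_21_23 == pytest.approx(
            truth.antisense_rpm[sample]["gene0"]
        )
        assert by_gene["gene0"].passes
        assert by_gene["gene1"].antisense_rpm_21_23 == pytest.approx(50.0)
        assert not by_gene["gene1"].passes

    def test_deterministic(self, toy_reference, tmp_path):
        config, ref = toy_reference
        small = SyntheticConfig(seed=9, smallrna_library_size=5_000,
                                smallrna_reads_per_group=100,
                                antisense_genes=())
        ref_s = build_toy_reference(small)
        p1, _ = simulate_smallrna(small, ref_s, tmp_path / "x")
        p2, _ = simulate_smallrna(small, ref_s, tmp_path / "y")
        (a,), (b,) = p1.values(), p2.values()
        assert _md5(a) == _md5(b)


class TestLocusTiling:
    def test_planted_segments_recovered_exactly(self, toy_reference, tmp_path):
        from retroquant.locus_metrics import compute_locus_coverage

        config, ref = toy_reference
        locus = ref.family_copies("L1Md_T")[0]  # length 1500
        segments = [(0, 900), (1000, 1380)]  # 1280/1500 = 85.333%
        path, expected = simulate_locus_tiling(
            ref, locus, segments, tmp_path / "tile.sam", read_len=60
        )
        cov = compute_locus_coverage(list(parse_alignments(path)), locus)
        assert cov.pct_covered == pytest.approx(expected["pct_covered"])
        assert cov.longest_run == expected["longest_run"] == 900

    def test_truth_json_round_trip(self, simulated_dataset, tmp_path):
        *_, truth = simulated_dataset
        path = tmp_path / "truth.json"
        truth.to_json(path)
        again = SyntheticTruth.from_json(path)
        assert again.subfamily_counts == truth.subfamily_counts
        assert again.library_sizes == truth.library_sizes
        assert again.locus_depth == truth.locus_depth
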