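"""Four-restriction counting, deduplication and RPM/RPKM normalization."""

import random

import numpy as np
import pytest

from conftest import make_locus, make_rec
from oracles import oracle_count
from retroquant.alignments import LibraryStats, PerfectPolicy
from retroquant.annotations import RepeatIndex
from retroquant.repeat_quant import (
    count_repeats,
    mean_over_replicates,
    normalize_rpkm,
    normalize_rpm,
    unit_annotated_lengths,
)

TWO_L1_COPIES = [
    make_locus("c1", 1000, 2000),
    make_locus("c2", 5000, 6000),
]


def _random_fixture(seed, n_reads=300, n_loci=12):
    rnd = random.Random(seed)
    loci = []
    families = ["L1Md_T", "L1Md_A", "IAPEz-int", "RLTR10"]
    groups = {"L1Md_T": "L1", "L1Md_A": "L1", "IAPEz-int": "IAP", "RLTR10": "ERVK"}
    for i in range(n_loci):
        fam = families[i % len(families)]
        start = rnd.randrange(0, 20000)
        loci.append(
            make_locus(f"L{i}", start, start + rnd.randrange(200, 800),
                       subfamily=fam, group=groups[fam])
        )
    recs = []
    for i in range(n_reads):
        # bias reads toward loci so containment actually happens
        if rnd.random() < 0.7 and loci:
            base = rnd.choice(loci)
            s = rnd.randrange(base.start - 20, base.end + 20)
        else:
            s = rnd.randrange(0, 21000)
        recs.append(
            make_rec(
                read_id=f"r{rnd.randrange(n_reads // 2)}",  # deliberate multimappers
                mate=rnd.choice([1, 2]),
                blocks=((s, s + rnd.randrange(30, 80)),),
                nm=rnd.choice([0, 0, 0, 1]),
            )
        )
    return loci, recs


class TestCounting:
    def test_multimapper_in_two_copies_of_one_subfamily_counts_once(self):
        recs = [
            make_rec(read_id="m", blocks=((1100, 1175),)),
            make_rec(read_id="m", blocks=((5100, 5175),), primary=False, nh=2),
        ]
        table = count_repeats(recs, RepeatIndex(TWO_L1_COPIES))
        assert table.counts.loc["L1Md_T", "raw_count"] == 1

    def test_boundary_straddling_read_contributes_zero(self):
        recs = [make_rec(blocks=((1950, 2010),))]  # ends 10 bp past the locus
        table = count_repeats(recs, RepeatIndex(TWO_L1_COPIES))
        assert table.counts["raw_count"].sum() == 0

    def test_read_in_two_subfamilies_counts_once_in_each(self):
        loci = [
            make_locus("a", 1000, 2000, subfamily="L1Md_T", group="L1"),
            make_locus("b", 900, 2100, subfamily="L1Md_A", group="L1"),
        ]
        recs = [make_rec(blocks=((1100, 1160),))]
        sub = count_repeats(recs, RepeatIndex(loci), level="subfamily")
        assert sub.counts.loc["L1Md_T", "raw_count"] == 1
        assert sub.counts.loc["L1Md_A", "raw_count"] == 1
        grp = count_repeats(recs, RepeatIndex(loci), level="group")
        assert grp.counts.loc["L1", "raw_count"] == 1  # deduplicated at group level

    def test_imperfect_read_never_counts(self):
        recs = [make_rec(blocks=((1100, 1160),), nm=1)]
        table = count_repeats(recs, RepeatIndex(TWO_L1_COPIES))
        assert table.counts["raw_count"].sum() == 0

    def test_empty_annotation_warns_and_is_all_zero(self):
        with pytest.warns(UserWarning, match="empty repeat annotation"):
            table = count_repeats([make_rec()], RepeatIndex([]))
        assert table.counts.empty

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("level", ["subfamily", "group"])
    def test_matches_brute_force_enumerator(self, seed, level):
        loci, recs = _random_fixture(seed)
        table = count_repeats(recs, RepeatIndex(loci), level=level)
        expected = oracle_count(recs, loci, level=level)
        got = {u: c for u, c in table.counts["raw_count"].items() if c > 0}
        assert got == expected

    def test_invariant_to_input_order_and_duplication(self):
        loci, recs = _random_fixture(99)
        index = RepeatIndex(loci)
        base = count_repeats(recs, index).counts["raw_count"]
        shuffled = list(recs)
        random.Random(1).shuffle(shuffled)
        assert base.equals(count_repeats(shuffled, index).counts["raw_count"])
        duplicated = recs + recs[:37]
        assert base.equals(count_repeats(duplicated, index).counts["raw_count"])

    def test_group_counts_bounded_by_subfamily_counts(self):
        loci, recs = _random_fixture(123)
        index = RepeatIndex(loci)
        sub = count_repeats(recs, index, level="subfamily").counts["raw_count"]
        grp = count_repeats(recs, index, level="group").counts["raw_count"]
        members = {}
        for loc in loci:
            members.setdefault(loc.group, set()).add(loc.subfamily)
        for group, subs in members.items():
            assert grp[group] >= max(sub[s] for s in subs)
            assert grp[group] <= sum(sub[s] for s in subs)

    def test_spliced_read_gap_must_stay_in_locus_by_default(self):
        # blocks inside the locus but the splice gap bridges past its end
        loci = [make_locus("a", 1000, 1200), make_locus("b", 1500, 1700)]
        rec = make_rec(blocks=((1100, 1150), (1550, 1600)), classes=("match", "skip"))
        strict = count_repeats([rec], RepeatIndex(loci))
        assert strict.counts["raw_count"].sum() == 0
        wide = make_locus("w", 900, 1800)
        contained = count_repeats([rec], RepeatIndex([wide]))
        assert contained.counts["raw_count"].sum() == 1


class TestNormalization:
    def test_rpm_arithmetic(self):
        table = count_repeats(
            [make_rec(blocks=((1100, 1160),), read_id=f"r{i}") for i in range(10)],
            RepeatIndex(TWO_L1_COPIES),
        )
        stats = LibraryStats("s", 2_000_000, 2_500_000)
        out = normalize_rpm(table, stats)
        assert out.counts.loc["L1Md_T", "rpm"] == pytest.approx(5.0)

    def test_zero_library_errors(self):
        table = count_repeats([], RepeatIndex(TWO_L1_COPIES))
        with pytest.raises(ValueError, match="zero perfect"):
            normalize_rpm(table, LibraryStats("s", 0, 0))

    def test_rpm_invariant_to_joint_scaling(self):
        loci, recs = _random_fixture(5)
        index = RepeatIndex(loci)
        table = count_repeats(recs, index)
        rpm1 = normalize_rpm(table, LibraryStats("s", 1000, 1000)).counts["rpm"]
        doubled = table.copy()
        doubled.counts["raw_count"] *= 2
        rpm2 = normalize_rpm(doubled, LibraryStats("s", 2000, 2000)).counts["rpm"]
        assert np.allclose(rpm1, rpm2)

    def test_rpkm_arithmetic_and_identity(self):
        table = count_repeats(
            [make_rec(blocks=((1100, 1160),), read_id=f"r{i}") for i in range(8)],
            RepeatIndex(TWO_L1_COPIES),
        )
        stats = LibraryStats("s", 2_000_000, 2_000_000)
        out = normalize_rpkm(normalize_rpm(table, stats), TWO_L1_COPIES)
        # total annotated length of L1Md_T is 2 kb
        assert out.counts.loc["L1Md_T", "rpkm"] == pytest.approx(
            out.counts.loc["L1Md_T", "rpm"] / 2.0
        )
        # algebraic identity rpkm * kb * millions = raw_count
        lengths = unit_annotated_lengths(TWO_L1_COPIES, "subfamily")
        for unit, row in out.counts.iterrows():
            kb = lengths[unit] / 1000
            assert row["rpkm"] * kb * (stats.n_perfect_read_units / 1e6) == pytest.approx(
                row["raw_count"]
            )

    def test_rpkm_ratio_follows_annotated_length(self):
        loci = [
            make_locus("a", 0, 1000, subfamily="A", group="GA"),
            make_locus("b", 5000, 7000, subfamily="B", group="GB"),
        ]
        recs = [make_rec(read_id=f"x{i}", blocks=((10, 60),)) for i in range(4)]
        recs += [make_rec(read_id=f"y{i}", blocks=((5010, 5060),)) for i in range(4)]
        table = normalize_rpm(
            count_repeats(recs, RepeatIndex(loci)), LibraryStats("s", 1_000_000, 1_000_000)
        )
        out = normalize_rpkm(table, loci)
        assert out.counts.loc["A", "rpkm"] == pytest.approx(
            2 * out.counts.loc["B", "rpkm"]
        )


class TestAggregation:
    def _table(self, rpm_by_unit, sample="s"):
        import pandas as pd

        from retroquant.repeat_quant import CountTable

        df = pd.DataFrame(
            {"raw_count": 0, "rpm": pd.Series(rpm_by_unit), "rpkm": np.nan}
        )
        df.index.name = "unit"
        return CountTable(sample, "subfamily", df, 1000)

    def test_mean_of_two_replicates(self):
        agg = mean_over_replicates(
            [self._table({"L1": 2.0}), self._table({"L1": 4.0})]
        )
        assert agg.mean_rpm["L1"] == pytest.approx(3.0)
        assert agg.n_replicates == 2

    def test_single_replicate_is_identity(self):
        agg = mean_over_replicates([self._table({"L1": 7.5, "IAP": 0.0})])
        assert agg.mean_rpm["L1"] == pytest.approx(7.5)

    def test_missing_unit_treated_as_zero(self):
        agg = mean_over_replicates(
            [self._table({"L1": 6.0}), self._table({"IAP": 2.0})]
        )
        assert agg.mean_rpm["L1"] == pytest.approx(3.0)
        assert agg.mean_rpm["IAP"] == pytest.approx(1.0)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            mean_over_replicates([])

    def test_recovers_planted_means_over_replicates(self):
        rng = np.random.default_rng(0)
        planted = {"A": 40.0, "B": 8.0}
        tables = [
            self._table({u: m + rng.normal(0, 0.5) for u, m in planted.items()})
            for _ in range(4)
        ]
        agg = mean_over_replicates(tables)
        for unit, mean in planted.items():
            assert agg.mean_rpm[unit] == pytest.approx(mean, abs=1.0)
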