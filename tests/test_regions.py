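"""CNVR construction: within-sample merge, cross-sample components,
typing, length filter, presence table."""

import numpy as np
import pytest

from cnvreg.intervals import Interval, Thresholds
from cnvreg.regions import (
    assign_type,
    build_cnvrs,
    cnvr_presence,
    filter_min_length,
    merge_within_sample,
)
from conftest import call, components_bruteforce


class TestWithinSampleMerge:
    def test_same_type_overlap_unions(self):
        merged = merge_within_sample(
            [call("chr1", 0, 100, type="loss"), call("chr1", 50, 150, type="loss")]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].type) == (0, 150, "loss")

    def test_different_types_kept_apart(self):
        calls = [call("chr1", 0, 100, type="loss"), call("chr1", 50, 150, type="gain")]
        merged = merge_within_sample(calls)
        assert sorted((m.start, m.end, m.type) for m in merged) == [
            (0, 100, "loss"), (50, 150, "gain")]

    def test_touching_calls_do_not_merge(self):
        merged = merge_within_sample(
            [call("chr1", 0, 100), call("chr1", 100, 200)]
        )
        assert len(merged) == 2

    def test_single_call_identity(self):
        c = call("chr1", 10, 20, cn=1.0)
        assert merge_within_sample([c]) == [c]

    def test_copy_number_length_weighted(self):
        merged = merge_within_sample(
            [call("chr1", 0, 100, cn=0.0), call("chr1", 50, 350, cn=1.0)]
        )
        assert merged[0].cn == pytest.approx((0.0 * 100 + 1.0 * 300) / 400)

    def test_missing_cn_propagates_as_absent(self):
        merged = merge_within_sample(
            [call("chr1", 0, 100, cn=None), call("chr1", 50, 150, cn=1.0)]
        )
        assert merged[0].cn is None

    def test_multiple_samples_rejected(self):
        with pytest.raises(ValueError, match="multiple samples"):
            merge_within_sample(
                [call("chr1", 0, 100, sample="a"), call("chr1", 0, 100, sample="b")]
            )


class TestBuildCnvrs:
    def test_worked_example_two_calls_span_union(self):
        # two calls a<c<b<d with reciprocal overlap 0.6 merge into [a, d)
        cnvrs = build_cnvrs(
            [call("chr1", 0, 100, sample="s1"), call("chr1", 40, 140, sample="s2")]
        )
        assert len(cnvrs) == 1
        assert (cnvrs[0].start, cnvrs[0].end) == (0, 140)
        assert cnvrs[0].frequency == 2

    def test_chaining_through_middle_call(self):
        # (1,3) reciprocal only 0.1 but both link via call 2 -> one CNVR
        cnvrs = build_cnvrs(
            [
                call("chr1", 0, 100, sample="s1"),
                call("chr1", 40, 140, sample="s2"),
                call("chr1", 90, 190, sample="s3"),
            ]
        )
        assert len(cnvrs) == 1
        assert (cnvrs[0].start, cnvrs[0].end) == (0, 190)

    def test_disjoint_calls_become_singletons(self):
        cnvrs = build_cnvrs(
            [call("chr1", 0, 100, sample="s1"), call("chr1", 5000, 5100, sample="s2")]
        )
        assert len(cnvrs) == 2
        assert all(len(v.members) == 1 for v in cnvrs)

    def test_partition_no_call_lost_or_duplicated(self):
        rng = np.random.default_rng(0)
        calls = _random_calls(rng, 150)
        cnvrs = build_cnvrs(calls)
        members = [m for v in cnvrs for m in v.members]
        assert sorted(members, key=id) is not None
        assert len(members) == len(calls)
        assert set(members) == set(calls)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_components(self, seed):
        rng = np.random.default_rng(seed)
        calls = _random_calls(rng, 200)
        cnvrs = build_cnvrs(calls)
        idx = {c: i for i, c in enumerate(calls)}
        got = {frozenset(idx[m] for m in v.members) for v in cnvrs}
        expected = components_bruteforce([c.interval for c in calls], 0.5)
        assert got == expected

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        calls = _random_calls(rng, 120)
        ref = [(v.id, v.start, v.end, v.type, v.carriers) for v in build_cnvrs(calls)]
        for _ in range(5):
            shuffled = list(calls)
            rng.shuffle(shuffled)
            got = [(v.id, v.start, v.end, v.type, v.carriers)
                   for v in build_cnvrs(shuffled)]
            assert got == ref

    def test_monotone_in_reciprocal_threshold(self):
        rng = np.random.default_rng(6)
        calls = _random_calls(rng, 150)
        counts = [
            len(build_cnvrs(calls, Thresholds(reciprocal_fraction=f)))
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts)

    def test_clique_mode_is_stricter_or_equal(self):
        rng = np.random.default_rng(7)
        calls = _random_calls(rng, 120)
        assert len(build_cnvrs(calls, clique=True)) >= len(build_cnvrs(calls))

    def test_ids_deterministic_and_sorted(self):
        rng = np.random.default_rng(8)
        calls = _random_calls(rng, 60)
        cnvrs = build_cnvrs(calls)
        assert [v.id for v in cnvrs] == sorted(v.id for v in cnvrs)
        keys = [(v.chrom, v.start) for v in cnvrs]
        assert keys == sorted(keys)


def _random_calls(rng, n):
    out = []
    for k in range(n):
        start = int(rng.integers(0, 30_000))
        length = int(rng.integers(100, 4_000))
        out.append(
            call(
                f"chr{rng.integers(1, 3)}", start, start + length,
                sample=f"s{rng.integers(0, 20)}",
                type=str(rng.choice(["loss", "gain"], p=[0.9, 0.1])),
            )
        )
    return out


@pytest.mark.parametrize(
    "types, expected",
    [
        (["loss", "loss"], "loss"),
        (["gain", "gain", "gain"], "gain"),
        (["loss", "gain"], "mixed"),
        (["gain"], "gain"),
    ],
)
def test_assign_type(types, expected):
    members = [call("chr1", 0, 100, sample=f"s{i}", type=t)
               for i, t in enumerate(types)]
    assert assign_type(members) == expected


def test_min_length_filter_boundary():
    cnvrs = build_cnvrs(
        [
            call("chr1", 0, 199, sample="s1"),
            call("chr1", 1000, 1200, sample="s1"),  # exactly 200 -> kept
            call("chr1", 5000, 403_900, sample="s1"),
        ]
    )
    kept = filter_min_length(cnvrs)
    assert [v.length for v in kept] == [200, 398_900]


def test_presence_table_sums():
    cnvrs = build_cnvrs(
        [
            call("chr1", 0, 1000, sample="s1"),
            call("chr1", 10, 1010, sample="s3"),
            call("chr2", 0, 500, sample="s2"),
        ]
    )
    table = cnvr_presence(cnvrs, ["s1", "s2", "s3"])
    assert list(table.sum(axis=1)) == [v.frequency for v in cnvrs]
    assert table.shape == (2, 3)
    first = table.iloc[0]
    assert list(first) == [1, 0, 1]


def test_presence_table_unknown_carrier_errors():
    cnvrs = build_cnvrs([call("chr1", 0, 1000, sample="mystery")])
    with pytest.raises(ValueError, match="mystery"):
        cnvr_presence(cnvrs, ["s1"])


def test_presence_table_empty():
    assert cnvr_presence([], ["s1", "s2"]).empty
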