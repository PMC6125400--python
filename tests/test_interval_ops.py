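"""Interval algebra vs per-base bitmap oracles, plus the printed-count arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from markconcord import reference
from markconcord.intervals import (
    SupportHistogram,
    build_consensus,
    merge_intervals,
    overlaps,
    summarize_overlap_fractions,
    support_histogram,
)
from markconcord.io_formats import Peak

from .conftest import random_peaks
from .oracles import bitmap_overlaps, brute_consensus, brute_support


class TestOverlaps:
    def test_identity_overlaps(self):
        assert overlaps(("chr1", 100, 200), ("chr1", 100, 200))

    def test_half_open_abutment_does_not_overlap(self):
        assert not overlaps(("chr1", 100, 200), ("chr1", 200, 300))

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(("chr1", 0, 100), ("chr2", 0, 100))

    def test_min_bp_threshold(self):
        a, b = ("chr1", 0, 10), ("chr1", 5, 20)
        assert overlaps(a, b, min_bp=5) and not overlaps(a, b, min_bp=6)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.tuples(st.integers(0, 300), st.integers(1, 50)),
        st.tuples(st.integers(0, 300), st.integers(1, 50)),
        st.integers(1, 10),
    )
    def test_agrees_with_per_base_intersection(self, a, b, min_bp):
        ia = ("chr1", a[0], a[0] + a[1])
        ib = ("chr1", b[0], b[0] + b[1])
        assert overlaps(ia, ib, min_bp) == bitmap_overlaps(ia, ib, min_bp)


class TestMerge:
    def test_overlapping_pair_merges(self):
        assert merge_intervals([("chr1", 0, 10), ("chr1", 5, 20)]) == [("chr1", 0, 20)]

    def test_abutting_pair_kept_separate(self):
        ivs = [("chr1", 0, 10), ("chr1", 10, 20)]
        assert merge_intervals(ivs) == ivs

    def test_random_intervals_preserve_base_coverage(self, rnd):
        from .oracles import overlap_components

        peaks = random_peaks(rnd, 200, chroms=("chr1", "chr2"))
        merged = merge_intervals(peaks)
        # same maximal groups as the pairwise-overlap-graph oracle
        assert merged == overlap_components([p.interval for p in peaks])
        # per-base coverage preserved exactly
        covered_in = {(c, b) for c, s, e in (p.interval for p in peaks) for b in range(s, e)}
        covered_out = {(c, b) for c, s, e in merged for b in range(s, e)}
        assert covered_in == covered_out
        # disjoint and sorted
        for (c1, s1, e1), (c2, s2, e2) in zip(merged, merged[1:]):
            assert (c1, e1) <= (c2, s2) or c1 < c2


class TestConsensus:
    def test_single_replicate_is_its_own_merge(self, rnd):
        peaks = random_peaks(rnd, 30)
        cons = build_consensus({"r1": peaks})
        assert [c.interval for c in cons] == merge_intervals(peaks)

    def test_identical_replicates_equal_merged_set(self, rnd):
        peaks = random_peaks(rnd, 40)
        cons = build_consensus({f"r{i}": list(peaks) for i in range(4)})
        assert [c.interval for c in cons] == merge_intervals(peaks)

    def test_zero_replicates_is_an_error(self):
        with pytest.raises(ValueError):
            build_consensus({})

    def test_every_replicate_contributes(self, rnd):
        reps = {f"r{i}": random_peaks(rnd, 25) for i in range(3)}
        for region in build_consensus(reps):
            assert set(region.contributing) == set(reps)
            assert all(len(v) >= 1 for v in region.contributing.values())
            # interval spans exactly the union of contributing peaks
            allp = [p for v in region.contributing.values() for p in v]
            assert region.start <= min(p.start for p in allp)
            assert region.end >= max(p.end for p in allp)

    def test_permutation_invariant_in_replicate_order(self, rnd):
        reps = {f"r{i}": random_peaks(rnd, 20) for i in range(4)}
        a = [c.interval for c in build_consensus(reps)]
        b = [c.interval for c in build_consensus(dict(reversed(list(reps.items()))))]
        assert a == b

    def test_idempotent_on_own_output(self, rnd):
        reps = {f"r{i}": random_peaks(rnd, 20) for i in range(4)}
        cons = [c.interval for c in build_consensus(reps)]
        as_peaks = [Peak(c, s, e) for c, s, e in cons]
        again = [c.interval for c in build_consensus({"self": as_peaks})]
        assert again == cons


class TestSupportHistogram:
    def test_empty_other_condition_gives_all_zero_support(self, rnd):
        cons = build_consensus({"r1": random_peaks(rnd, 20)})
        hist = support_histogram(cons, {"b1": [], "b2": []})
        assert hist.counts[0] == hist.total == len(cons)

    def test_identical_other_condition_gives_full_support(self, rnd):
        peaks = random_peaks(rnd, 30)
        cons = build_consensus({"r1": list(peaks), "r2": list(peaks)})
        hist = support_histogram(cons, {"b1": list(peaks), "b2": list(peaks), "b3": list(peaks)})
        assert hist.counts[3] == hist.total

    def test_counts_conserve_total(self, rnd):
        reps = {f"r{i}": random_peaks(rnd, 25) for i in range(4)}
        other = {f"b{i}": random_peaks(rnd, 25) for i in range(4)}
        cons = build_consensus(reps)
        hist = support_histogram(cons, other)
        assert sum(hist.counts) == hist.total == len(cons)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            SupportHistogram("x", [1, 2], 4)


class TestOracleEquivalence:
    def test_consensus_and_support_match_bruteforce_on_random_instances(self, rnd):
        for _ in range(25):
            reps = {f"r{i}": random_peaks(rnd, rnd.randrange(1, 50)) for i in range(4)}
            other = {f"b{i}": random_peaks(rnd, rnd.randrange(1, 50)) for i in range(4)}
            cons = build_consensus(reps)
            assert [c.interval for c in cons] == brute_consensus(reps)
            hist = support_histogram(cons, other)
            brute = brute_support([c.interval for c in cons], other)
            assert [c.other_support for c in cons] == brute
            assert hist.counts == [brute.count(k) for k in range(5)]


class TestOverlapFractions:
    def test_reported_control_side_percentages(self):
        hist = SupportHistogram(
            "control", reference.CONTROL_SUPPORT_COUNTS,
            sum(reference.CONTROL_SUPPORT_COUNTS),
        )
        assert summarize_overlap_fractions(hist) == [0.44, 3.14, 5.92, 13.29, 77.21]

    def test_reported_treatment_side_percentages(self):
        hist = SupportHistogram(
            "ethanol", reference.ETHANOL_SUPPORT_COUNTS,
            sum(reference.ETHANOL_SUPPORT_COUNTS),
        )
        assert summarize_overlap_fractions(hist) == [1.79, 9.15, 12.80, 16.12, 60.14]

    def test_half_up_rounding_at_ties(self):
        hist = SupportHistogram("x", [1, 3999], 4000)  # exactly 0.025 %
        assert summarize_overlap_fractions(hist)[0] == 0.03  # ties go up, not to even

    def test_empty_histogram_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_overlap_fractions(SupportHistogram("x", [0, 0], 0))
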