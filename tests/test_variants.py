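import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampdel._seq import revcomp
from ampdel.align import DeletionEvent, InsertionEvent, ReadAlignment
from ampdel.reference import AmpliconReference
from ampdel.simdata import random_sequence
from ampdel.variants import (
    ClassificationConfig,
    LDPattern,
    classify_mmej,
    classify_symmetry,
    classify_variant,
    cluster_ld_patterns,
    detect_microhomology,
    map_insertion_origin,
    tabulate_small_indels,
)

from _oracles import max_right_flank_overlap, scan_best_ungapped_hit, seed_linkage_clusters

CFG = ClassificationConfig()


def aln(events, aligned=True, rid="r"):
    return ReadAlignment(rid, aligned, events, 0, [(0, 5000)])


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (49, "small_indel"),
            (50, "intermediate_deletion"),
            (199, "intermediate_deletion"),
            (200, "large_deletion"),
            (300, "large_deletion"),
        ],
    )
    def test_deletion_size_boundaries(self, size, expected):
        call = classify_variant(aln([DeletionEvent(1000, 1000 + size)]), CFG)
        assert call.category == expected

    @pytest.mark.parametrize(
        "size,expected", [(49, "small_indel"), (50, "large_insertion")]
    )
    def test_insertion_boundary(self, size, expected):
        call = classify_variant(aln([InsertionEvent(1000, "A" * size)]), CFG)
        assert call.category == expected

    def test_insertion_with_deletion(self):
        call = classify_variant(
            aln([DeletionEvent(1000, 1400), InsertionEvent(2000, "A" * 60)]), CFG
        )
        assert call.category == "insertion_with_deletion"

    def test_large_insertion_with_small_deletion_stays_insertion(self):
        call = classify_variant(
            aln([DeletionEvent(1000, 1005), InsertionEvent(2000, "A" * 60)]), CFG
        )
        assert call.category == "large_insertion"

    def test_junction_insertion_counts(self):
        call = classify_variant(
            aln([DeletionEvent(1000, 1400, junction_insertion="A" * 70)]), CFG
        )
        assert call.category == "insertion_with_deletion"

    def test_unmodified_and_invalid(self):
        assert classify_variant(aln([]), CFG).category == "unmodified"
        assert classify_variant(aln([], aligned=False), CFG).category == "invalid"

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        alns = []
        for i in range(200):
            events = []
            if rng.random() < 0.8:
                start = int(rng.integers(0, 2000))
                events.append(DeletionEvent(start, start + int(rng.integers(1, 1000))))
            if rng.random() < 0.3:
                events.append(InsertionEvent(3000, "A" * int(rng.integers(1, 120))))
            alns.append(aln(events, aligned=rng.random() > 0.05, rid=f"r{i}"))
        calls = [classify_variant(a, CFG) for a in alns]
        from collections import Counter

        counts = Counter(c.category for c in calls)
        assert sum(counts.values()) == len(alns)
        assert set(counts) <= {
            "unmodified",
            "small_indel",
            "intermediate_deletion",
            "large_deletion",
            "large_insertion",
            "insertion_with_deletion",
            "invalid",
        }


def ld_calls(pairs_with_counts):
    calls = []
    i = 0
    for (start, size), n in pairs_with_counts:
        for _ in range(n):
            calls.append(
                classify_variant(aln([DeletionEvent(start, start + size)], rid=f"c{i}"), CFG)
            )
            i += 1
    return calls


class TestClusterLdPatterns:
    def test_within_tolerance_merged(self):
        patterns = cluster_ld_patterns(ld_calls([((100, 300), 5), ((105, 305), 1)]), CFG)
        assert len(patterns) == 1
        assert patterns[0].count == 6
        assert (patterns[0].rep_start, patterns[0].rep_size) == (100, 300)

    def test_start_beyond_tolerance_split(self):
        patterns = cluster_ld_patterns(ld_calls([((100, 300), 1), ((120, 300), 1)]), CFG)
        assert len(patterns) == 2

    def test_counts_conserved(self):
        data = [((100, 300), 5), ((105, 305), 1), ((400, 250), 2)]
        patterns = cluster_ld_patterns(ld_calls(data), CFG)
        assert sum(p.count for p in patterns) == sum(n for _, n in data)

    def test_rejects_non_ld_call(self):
        with pytest.raises(ValueError):
            cluster_ld_patterns([classify_variant(aln([DeletionEvent(0, 60)]), CFG)], CFG)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_seed_linkage_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        n_patterns = int(rng.integers(1, 20))
        pairs = {}
        for _ in range(n_patterns):
            key = (int(rng.integers(500, 560)), int(rng.integers(200, 260)))
            pairs[key] = pairs.get(key, 0) + int(rng.integers(1, 8))
        data_list = list(pairs.items())
        patterns = cluster_ld_patterns(ld_calls(data_list), CFG)
        expected = seed_linkage_clusters(data_list)
        # compare cluster compositions as sets of (start, size) pairs
        id_to_pair = {}
        i = 0
        for (start, size), n in data_list:
            for _ in range(n):
                id_to_pair[f"c{i}"] = (start, size)
                i += 1
        got_frozen = {
            frozenset({id_to_pair[cid] for cid in p.member_ids}) for p in patterns
        }
        assert got_frozen == set(expected)

    def test_monotonic_in_tolerance(self):
        rng = np.random.default_rng(12)
        data_list = [
            ((int(rng.integers(500, 600)), int(rng.integers(200, 300))), int(rng.integers(1, 5)))
            for _ in range(15)
        ]
        counts = []
        for tol in (0, 5, 10, 20, 40):
            cfg = ClassificationConfig(cluster_size_tol=tol, cluster_start_tol=tol)
            counts.append(len(cluster_ld_patterns(ld_calls(data_list), cfg)))
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def sym_ref():
    return AmpliconReference("r", "A" * 3000, cut_site=1500)


class TestClassifySymmetry:

    def test_centered_symmetric(self, sym_ref):
        p = LDPattern(1400, 200, [], 1)  # midpoint 1500 == cut
        assert classify_symmetry(p, sym_ref, CFG) == "symmetric"
        assert p.delta == 0

    def test_upstream(self, sym_ref):
        # size 200, midpoint 15 left of cut -> delta 0.075
        p = LDPattern(1385, 200, [], 1)
        assert classify_symmetry(p, sym_ref, CFG) == "upstream"
        assert p.delta == pytest.approx(0.075)

    def test_boundary_inclusive(self, sym_ref):
        # size 400, midpoint 20 right of cut -> delta exactly 0.05
        p = LDPattern(1320, 400, [], 1)
        assert classify_symmetry(p, sym_ref, CFG) == "symmetric"
        assert p.delta == pytest.approx(0.05)

    def test_downstream(self, sym_ref):
        p = LDPattern(1500, 300, [], 1)
        assert classify_symmetry(p, sym_ref, CFG) == "downstream"

    @given(st.integers(-200, 200), st.integers(1200, 1400), st.integers(200, 400))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, shift, start, size):
        ref_a = AmpliconReference("a", "A" * 4000, cut_site=1500)
        ref_b = AmpliconReference("b", "A" * 4000, cut_site=1500 + shift)
        pa = LDPattern(start, size, [], 1)
        pb = LDPattern(start + shift, size, [], 1)
        side_a = classify_symmetry(pa, ref_a, CFG)
        side_b = classify_symmetry(pb, ref_b, CFG)
        assert side_a == side_b
        assert pa.delta == pytest.approx(pb.delta)


class TestMicrohomology:
    def test_ctgcc_worked_example(self):
        left = "GATTACAGATTACAGATTAC"
        ref_seq = left + "CTGCCTTTT" + "CTGCC" + "AGGAGGAGGAGGAGGAGGAG"
        # deletion of the 9-base block CTGCCTTTT leaves ...CTGCC...
        dele = DeletionEvent(20, 29)
        mh, length = detect_microhomology(ref_seq, dele)
        assert mh == "CTGCC"
        assert length == 5

    def test_no_homology(self):
        ref_seq = "AAAACCCCGGGGTTTT"
        mh, length = detect_microhomology(ref_seq, DeletionEvent(4, 8))
        assert length == 0
        assert mh == ""

    def test_rejects_junction_insertion(self):
        with pytest.raises(ValueError):
            detect_microhomology("ACGTACGT", DeletionEvent(2, 4, junction_insertion="T"))

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_enumeration_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        seq = "".join("ACG"[i] for i in rng.integers(0, 3, 60))
        start = int(rng.integers(0, 40))
        end = int(rng.integers(start + 1, min(start + 15, 60)))
        _, length = detect_microhomology(seq, DeletionEvent(start, end))
        assert length == max_right_flank_overlap(seq, start, end)


class TestClassifyMmej:
    @pytest.mark.parametrize("size,expected", [(3, True), (2, False), (1, False), (10, True)])
    def test_size_threshold(self, size, expected):
        call = classify_variant(aln([DeletionEvent(100, 100 + size)]), CFG)
        assert classify_mmej(call, CFG) is expected

    def test_insertion_not_mmej(self):
        call = classify_variant(aln([InsertionEvent(100, "AAAA")]), CFG)
        assert classify_mmej(call, CFG) is False

    def test_non_small_indel_rejected(self):
        call = classify_variant(aln([DeletionEvent(100, 400)]), CFG)
        with pytest.raises(ValueError):
            classify_mmej(call, CFG)


@pytest.fixture(scope="module")
def candidates():
    rng = np.random.default_rng(16)
    return {
        "locusA": random_sequence(600, rng),
        "locusB": random_sequence(600, rng),
    }


class TestMapInsertionOrigin:

    def test_reverse_complement_window(self, candidates):
        insert = revcomp(candidates["locusA"][200:400])
        hit = map_insertion_origin(insert, candidates)
        assert hit is not None
        assert hit.candidate == "locusA"
        assert hit.strand == "inverted"
        assert hit.mismatch_fraction == 0.0
        assert hit.offset == 200

    def test_unrelated_insert_none(self, candidates):
        rng = np.random.default_rng(17)
        assert map_insertion_origin(random_sequence(200, rng), candidates) is None

    def test_substituted_insert_found(self, candidates):
        rng = np.random.default_rng(18)
        window = list(candidates["locusB"][100:300])
        for pos in rng.choice(200, size=10, replace=False):  # 5% substitutions
            window[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[pos]]
        hit = map_insertion_origin("".join(window), candidates)
        assert hit is not None
        assert hit.candidate == "locusB"
        assert hit.offset == 100
        assert hit.mismatch_fraction == pytest.approx(0.05)

    def test_exhaustive_scan_oracle(self, candidates):
        rng = np.random.default_rng(19)
        for _ in range(5):
            off = int(rng.integers(0, 500))
            insert = candidates["locusA"][off : off + 80]
            if rng.random() < 0.5:
                insert = revcomp(insert)
            hit = map_insertion_origin(insert, candidates)
            expected = scan_best_ungapped_hit(insert, candidates)
            assert hit.mismatch_fraction == pytest.approx(expected[0])
            assert (hit.strand == "inverted") == expected[1]
            assert hit.offset == expected[2]
            assert hit.candidate == expected[3]

    def test_empty_candidates_warns(self):
        with pytest.warns(UserWarning):
            assert map_insertion_origin("A" * 60, {}) is None


@pytest.fixture(scope="module")
def indel_ref():
    return AmpliconReference("r", random_sequence(2000, np.random.default_rng(20)), 1000)


class TestTabulateSmallIndels:

    def test_all_unmodified(self, indel_ref):
        calls = [classify_variant(aln([], rid=f"r{i}"), CFG) for i in range(5)]
        profile = tabulate_small_indels(calls, indel_ref)
        assert profile.histogram == {}
        assert profile.position_frequency.max() == 0

    def test_ten_nine_base_deletions(self, indel_ref):
        calls = [
            classify_variant(aln([DeletionEvent(996, 1005)], rid=f"r{i}"), CFG)
            for i in range(10)
        ]
        profile = tabulate_small_indels(calls, indel_ref)
        assert profile.histogram == {-9: 10}
        assert profile.mmej_fraction == 1.0

    def test_events_outside_window_ignored(self, indel_ref):
        calls = [classify_variant(aln([DeletionEvent(100, 110)]), CFG)]
        profile = tabulate_small_indels(calls, indel_ref, window=30)
        assert profile.histogram == {}

    def test_rejects_large_categories(self, indel_ref):
        call = classify_variant(aln([DeletionEvent(500, 900)]), CFG)
        with pytest.raises(ValueError):
            tabulate_small_indels([call], indel_ref)

    def test_simulated_spectrum_recovered(self, indel_ref):
        rng = np.random.default_rng(22)
        design = {-9: 0.5, -3: 0.3, 2: 0.2}
        calls = []
        for i in range(500):
            size = rng.choice(list(design), p=list(design.values()))
            if size < 0:
                ev = DeletionEvent(1000, 1000 - size)
            else:
                ev = InsertionEvent(1000, "A" * size)
            calls.append(classify_variant(aln([ev], rid=f"r{i}"), CFG))
        profile = tabulate_small_indels(calls, indel_ref)
        total = sum(profile.histogram.values())
        for size, frac in design.items():
            assert profile.histogram[size] / total == pytest.approx(frac, abs=0.06)
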