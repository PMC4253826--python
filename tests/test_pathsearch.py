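import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybridec import (
    SearchParams,
    SearchStatus,
    Direction,
    best_prefix_alignment,
    bridge_search,
    edit_distance,
    extension_search,
)
from tests.conftest import make_index, perfect_index, random_dna
from tests.helpers import best_bridge_by_enumeration, levenshtein

dna = st.text(alphabet="ACGT", max_size=12)


class TestEditDistance:
    @pytest.mark.parametrize("a,b,d", [
        ("", "ACG", 3),
        ("ACG", "", 3),
        ("ACGT", "ACGT", 0),
        ("ACGT", "AGT", 1),
        ("AAAA", "TTTT", 4),
    ])
    def test_examples(self, a, b, d):
        assert edit_distance(a, b) == d

    @given(dna, dna, dna)
    def test_metric_properties(self, a, b, c):
        assert edit_distance(a, b) == edit_distance(b, a)
        assert edit_distance(a, b) <= edit_distance(a, c) + edit_distance(c, b)
        assert (edit_distance(a, b) == 0) == (a == b)

    @given(dna, dna)
    def test_agrees_with_plain_dp(self, a, b):
        assert edit_distance(a, b) == levenshtein(a, b)


def _mutate(seq, pos, kind, base="A"):
    if kind == "sub":
        alt = "C" if seq[pos] != "C" else "G"
        return seq[:pos] + alt + seq[pos + 1:]
    if kind == "ins":
        return seq[:pos] + base + seq[pos:]
    return seq[:pos] + seq[pos + 1:]


class TestBridgeSearch:
    k = 5

    def _params(self, **kw):
        # at k=5 the canonical graph has many strand-shadow junctions, so
        # even short exact regions need a roomy branch budget
        defaults = dict(max_error_rate=0.4, branching_limit=500_000,
                        target_count=5, max_region_span=500)
        defaults.update(kw)
        return SearchParams(**defaults)

    def test_unique_path_identity(self, small_genome):
        s = small_genome[200:240]  # no short tandem repeats in this window
        idx = perfect_index(s, k=self.k)
        res = bridge_search(s[: self.k], s[-self.k:], s, idx, self._params())
        assert res.status is SearchStatus.FOUND
        assert res.path_seq == s
        assert res.edit_dist == 0

    def test_diamond_graph_selects_matching_variant(self, rng):
        # two variants differing at one interior base
        base = random_dna(rng, 30)
        v1 = base
        v2 = _mutate(base, 15, "sub")
        idx = make_index([v1, v1, v2, v2], k=self.k, solid_threshold=2)
        source, target = base[: self.k], base[-self.k:]
        params = self._params()
        budget = math.ceil(0.4 * len(v1))

        res = bridge_search(source, target, v1, idx, params)
        oracle = best_bridge_by_enumeration(idx, source, target, v1, budget)
        assert res.status is SearchStatus.FOUND
        assert res.edit_dist == 0 == oracle[0]
        assert res.path_seq == v1 == oracle[1]

        # same region with one inserted base: distance 1, same path
        region2 = _mutate(v1, 12, "ins")
        res2 = bridge_search(source, target, region2, idx, params)
        oracle2 = best_bridge_by_enumeration(idx, source, target, region2,
                                             math.ceil(0.4 * len(region2)))
        assert res2.status is SearchStatus.FOUND
        assert res2.edit_dist == 1 == oracle2[0]
        assert res2.path_seq == v1

    def test_found_distance_is_true_edit_distance(self, rng):
        base = random_dna(rng, 40)
        idx = perfect_index(base, k=self.k)
        region = _mutate(_mutate(base, 20, "del"), 10, "sub")
        res = bridge_search(base[: self.k], base[-self.k:], region, idx,
                            self._params())
        assert res.status is SearchStatus.FOUND
        assert res.edit_dist == levenshtein(res.path_seq, region)
        assert res.edit_dist <= math.ceil(0.4 * len(region))

    def test_no_path_when_graph_disconnected(self, rng):
        left = random_dna(rng, 12)
        right = random_dna(rng, 12)
        idx = make_index([left, right], k=self.k)
        region = left + right
        res = bridge_search(left[: self.k], right[-self.k:], region, idx,
                            self._params())
        assert res.status is SearchStatus.NO_PATH

    def test_aborts_at_branching_limit_one(self):
        # first divergence precedes any completion on the wrong branch:
        # two bubbles force >1 branch alternative before the target
        stem = "ACGTC"
        v1 = stem + "AAGGC" + "TACGA"
        v2 = stem + "CAGGC" + "TACGA"
        idx = make_index([v1, v2], k=3, solid_threshold=1)
        region = v1
        res = bridge_search(region[:3], region[-3:], region, idx,
                            SearchParams(max_error_rate=0.9,
                                         branching_limit=1))
        assert res.status is SearchStatus.ABORTED

    def test_monotone_in_branching_limit(self, rng):
        base = random_dna(rng, 30)
        v2 = _mutate(base, 14, "sub")
        idx = make_index([base, v2], k=self.k)
        region = _mutate(base, 15, "ins")
        dists = []
        for limit in (2, 10, 1000):
            res = bridge_search(base[: self.k], base[-self.k:], region, idx,
                                self._params(branching_limit=limit))
            if res.status is SearchStatus.FOUND:
                dists.append(res.edit_dist)
        assert dists == sorted(dists, reverse=True)

    def test_rejects_malformed_region(self, small_genome):
        idx = perfect_index(small_genome[:30], k=self.k)
        with pytest.raises(ValueError):
            bridge_search("ACGTA", "ACGTA", "ACGTAA", idx, self._params())


class TestExtensionSearch:
    # k = 9: at k = 5 almost every 60 bp window (plus its reverse-strand
    # shadow) repeats some 4-mer, which makes one-anchor extension
    # legitimately ambiguous and exactness unattainable
    k = 9

    def _params(self, **kw):
        defaults = dict(max_error_rate=0.4, branching_limit=500_000)
        defaults.update(kw)
        return SearchParams(**defaults)

    def test_exact_tail(self, small_genome):
        # repeat-free window: a tandem repeat would make the one-anchor
        # search legitimately ambiguous
        seg = small_genome[200:230]
        idx = perfect_index(small_genome[200:260], k=self.k)
        res = extension_search(seg[: self.k], seg, Direction.TAIL, idx,
                               self._params())
        assert res.status is SearchStatus.FOUND
        assert res.trimmed_seq == seg
        assert res.segment_consumed == len(seg)
        assert res.score == len(seg)

    def test_exact_head_by_reverse_complement(self, small_genome):
        seg = small_genome[200:230]
        idx = perfect_index(small_genome[200:260], k=self.k)
        res = extension_search(seg[-self.k:], seg, Direction.HEAD, idx,
                               self._params())
        assert res.status is SearchStatus.FOUND
        assert res.trimmed_seq == seg
        assert res.trimmed_seq.endswith(seg[-self.k:])

    def test_divergent_graph_trims_to_matching_prefix(self, rng):
        # graph path matches the first m bases then diverges with no
        # alternative; the trimmed extension must keep >= m matching bases
        m = 18
        common = random_dna(rng, m)
        graph_path = common + "ACACAC"
        segment = common + "GTGTGT"
        idx = make_index([graph_path], k=self.k)
        res = extension_search(segment[: self.k], segment, Direction.TAIL,
                               idx, self._params())
        assert res.status is SearchStatus.FOUND
        assert len(res.trimmed_seq) >= m
        # oracle: exhaustive DP over every (path prefix, segment prefix)
        best = max(
            max(_score(res.path_seq[:i], segment[:j])
                for j in range(len(segment) + 1))
            for i in range(self.k, len(res.path_seq) + 1)
        )
        assert res.score == best

    def test_anchor_without_successor(self):
        idx = make_index(["AAACC"], k=5, solid_threshold=1)
        res = extension_search("AAACC", "AAACCGGTT", Direction.TAIL, idx,
                               self._params())
        assert res.status is SearchStatus.NO_PATH

    def test_rejects_segment_not_anchored(self, small_genome):
        idx = perfect_index(small_genome[:30], k=self.k)
        with pytest.raises(ValueError):
            extension_search(small_genome[:5], "TTTTTTTT", Direction.TAIL,
                             idx, self._params())


def _score(a: str, b: str) -> int:
    """Plain global alignment score: match +1, mismatch/gap -1."""
    prev = [-j for j in range(len(b) + 1)]
    for i, ca in enumerate(a, 1):
        cur = [-i]
        for j, cb in enumerate(b, 1):
            cur.append(max(prev[j] - 1, cur[j - 1] - 1,
                           prev[j - 1] + (1 if ca == cb else -1)))
        prev = cur
    return prev[-1]


class TestBestPrefixAlignment:
    def test_identical(self):
        n, score, used = best_prefix_alignment("ACGTACGT", "ACGTACGT")
        assert (n, score, used) == (8, 8, 8)

    def test_trailing_garbage_trimmed(self):
        seg = "ACGTACGTAC"
        path = seg + "GGGG"
        n, score, used = best_prefix_alignment(path, seg)
        assert n == len(seg)
        assert score == len(seg)

    def test_anchor_only(self):
        n, score, used = best_prefix_alignment("ACGTA", "ACGTACC",
                                               min_len=5)
        assert n == 5

    @given(st.text(alphabet="ACGT", min_size=1, max_size=8),
           st.text(alphabet="ACGT", min_size=1, max_size=8))
    def test_matches_exhaustive_prefix_dp(self, path, seg):
        n, score, used = best_prefix_alignment(path, seg)
        oracle = max(
            (max(_score(path[:i], seg[:j]) for j in range(len(seg) + 1)), i)
            for i in range(1, len(path) + 1)
        )
        assert score == oracle[0]
        assert n == oracle[1]
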