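"""MoC, conservation, shared boundaries, and size scaling — each operation
checked against hand evaluations or quadratic brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tadconcord as tc
from tadconcord.concordance import (
    conservation_ratio,
    conserved_boundaries,
    conserved_tads,
    cross_resolution_conserved,
    moc,
    moc_detail,
    shared_boundaries,
    size_summary,
)
from tadconcord.core import ValidationError

from conftest import random_partition


# ------------------------------------------------------------------- MoC
class TestMoc:
    def test_hand_evaluated_example(self):
        # (0.8 + 1/30 + 5/6 - 1) / (sqrt(4) - 1) = 2/3
        p = tc.TadPartition("c", [(1, 40), (41, 100)], 1)
        q = tc.TadPartition("c", [(1, 50), (51, 100)], 1)
        assert abs(moc(p, q) - 2.0 / 3.0) < 1e-12
        assert moc(p, q) == moc(q, p)

    def test_self_concordance_is_exactly_one(self, rng):
        for _ in range(20):
            p = random_partition(rng)
            assert moc(p, p) == 1.0

    def test_single_cluster_vs_many_is_exactly_zero(self):
        one = tc.TadPartition("c", [(1, 2000)], 100)
        tiles = np.arange(20)
        q = tc.TadPartition(
            "c", np.column_stack([tiles * 100 + 1, tiles * 100 + 100]), 100
        )
        assert moc(one, q) == 0.0
        assert moc(q, one) == 0.0

    def test_both_single_cluster_returns_one(self):
        p = tc.TadPartition("c", [(1, 100)], 100)
        q = tc.TadPartition("c", [(1, 100)], 100)
        assert moc(p, q) == 1.0

    def test_gaps_count_as_clusters(self):
        # p covers [1,100] as one TAD; q has a TAD [1,50] and a gap [51,100]:
        # identical clusterings once the gap becomes a cluster would need
        # matching intervals — here overlap table is computed over 1 vs 2
        # clusters: sum = 50^2/(100*50) + 50^2/(100*50) = 1 -> MoC 0
        p = tc.TadPartition("c", [(1, 100)], 100, chrom_length_bp=100)
        q = tc.TadPartition("c", [(1, 50)], 50, chrom_length_bp=100)
        assert moc(p, q) == 0.0
        # whereas q vs a partition with the same TAD+gap structure is 1
        q2 = tc.TadPartition("c", [(1, 50)], 50, chrom_length_bp=100)
        assert moc(q, q2) == 1.0

    def test_span_harmonization_pads_shorter_side(self):
        p = tc.TadPartition("c", [(1, 100)], 100)
        q = tc.TadPartition("c", [(1, 100), (101, 200)], 100)
        # union span 200: p's clusters become [1,100]+gap[101,200]
        detail = moc_detail(p, q)
        assert detail.clusters_a.tolist() == [[1, 100], [101, 200]]
        assert detail.moc == 1.0

    def test_different_chromosomes_rejected(self):
        p = tc.TadPartition("chr1", [(1, 100)], 100)
        q = tc.TadPartition("chr2", [(1, 100)], 100)
        with pytest.raises(ValidationError):
            moc(p, q)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = random_partition(rng)
        q = random_partition(rng)
        a, b = moc(p, q), moc(q, p)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0

    def test_overlap_table_accounts_for_whole_span(self, rng):
        p = random_partition(rng)
        q = random_partition(rng)
        d = moc_detail(p, q)
        span = max(p.span_end_bp, q.span_end_bp)
        assert sum(ov for _, _, ov in d.overlaps) == span


# ------------------------------------------------------ boundary conservation
def oracle_conserved_edges(ep, eq, radius):
    return np.array([any(abs(x - y) <= radius for y in eq) for x in ep], dtype=bool)


class TestConservedBoundaries:
    def test_identical_partitions_all_conserved_at_radius_zero(self, rng):
        p = random_partition(rng)
        r = conserved_boundaries(p, p, 0)
        assert r.fraction_a == 1.0 and r.fraction_b == 1.0

    def test_offset_three_bins_threshold(self):
        b = 10_000
        p = tc.TadPartition("c", [(1, 10 * b), (10 * b + 1, 20 * b)], b,
                            chrom_length_bp=40 * b)
        # all q boundaries shifted +3 bins
        q = tc.TadPartition("c", [(3 * b + 1, 13 * b), (13 * b + 1, 23 * b)], b,
                            chrom_length_bp=40 * b)
        assert conserved_boundaries(p, q, 2).fraction_a == 0.0
        assert conserved_boundaries(p, q, 3).fraction_a == 1.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            p = random_partition(rng, n_bins=80, max_domains=10)
            q = random_partition(rng, n_bins=80, max_domains=10)
            radius = int(rng.integers(0, 6))
            r = conserved_boundaries(p, q, radius)
            assert np.array_equal(
                r.conserved_a, oracle_conserved_edges(p.boundaries(), q.boundaries(), radius)
            )
            assert np.array_equal(
                r.conserved_b, oracle_conserved_edges(q.boundaries(), p.boundaries(), radius)
            )

    def test_fraction_nondecreasing_in_radius(self, rng):
        for _ in range(10):
            p = random_partition(rng)
            q = random_partition(rng)
            fr = [conserved_boundaries(p, q, r).fraction_a for r in range(6)]
            assert fr == sorted(fr)

    def test_unequal_bin_sizes_rejected(self):
        p = tc.TadPartition("c", [(1, 100)], 100)
        q = tc.TadPartition("c", [(1, 100)], 50)
        with pytest.raises(ValidationError, match="cross_resolution"):
            conserved_boundaries(p, q, 1)


# ---------------------------------------------------------- TAD conservation
def oracle_conserved_tads(p, q, radius):
    out = []
    for s, e in zip(p.start_edges, p.end_edges):
        out.append(
            any(
                abs(qs - s) <= radius and abs(qe - e) <= radius
                for qs, qe in zip(q.start_edges, q.end_edges)
            )
        )
    return np.array(out, dtype=bool)


class TestConservedTads:
    def test_identical_partitions_all_conserved(self, rng):
        p = random_partition(rng)
        assert conserved_tads(p, p, 0).fraction_a == 1.0

    def test_spanning_two_tads_not_conserved(self):
        b = 10_000
        # p-TAD [1, 20] bins; q splits it into [1,10] and [11,20]: p's outer
        # boundaries coincide with boundaries of two DIFFERENT q TADs
        p = tc.TadPartition("c", [(1, 20 * b)], b)
        q = tc.TadPartition("c", [(1, 10 * b), (10 * b + 1, 20 * b)], b)
        assert conserved_tads(p, q, 0).n_conserved_a == 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            p = random_partition(rng, n_bins=100, max_domains=12)
            q = random_partition(rng, n_bins=100, max_domains=12)
            radius = int(rng.integers(0, 4))
            r = conserved_tads(p, q, radius)
            assert np.array_equal(r.conserved_a, oracle_conserved_tads(p, q, radius))
            assert np.array_equal(r.conserved_b, oracle_conserved_tads(q, p, radius))


class TestCrossResolution:
    def test_refinement_fully_conserved(self):
        coarse = tc.TadPartition("c", [(1, 50_000), (50_001, 150_000)], 50_000)
        fine = tc.TadPartition(
            "c", [(1, 20_000), (20_001, 50_000), (50_001, 150_000)], 10_000
        )
        assert cross_resolution_conserved(coarse, fine).fraction_a == 1.0

    def test_interior_fine_boundaries_not_conserved(self):
        coarse = tc.TadPartition("c", [(100_001, 400_000)], 100_000)
        # fine boundaries fall in the middle coarse bin, strictly away from
        # both coarse boundary bins
        fine = tc.TadPartition("c", [(210_001, 240_000)], 10_000)
        res = cross_resolution_conserved(coarse, fine)
        assert res.fraction_a == 0.0

    def test_matches_membership_oracle(self, rng):
        for _ in range(20):
            fine = random_partition(rng, n_bins=100, bin_size_bp=10_000)
            coarse = random_partition(rng, n_bins=20, bin_size_bp=50_000)
            res = cross_resolution_conserved(coarse, fine)
            fine_bp = fine.boundaries() * fine.bin_size_bp
            expected = []
            for bin_idx, kind in sorted(set(coarse.boundary_records())):
                lo, hi = bin_idx * 50_000, (bin_idx + 1) * 50_000
                expected.append(any(lo <= f <= hi for f in fine_bp))
            assert res.conserved_a.tolist() == expected

    def test_non_multiple_bin_sizes_rejected(self):
        coarse = tc.TadPartition("c", [(1, 30_000)], 30_000)
        fine = tc.TadPartition("c", [(1, 20_000)], 20_000)
        with pytest.raises(ValidationError):
            cross_resolution_conserved(coarse, fine)


# ----------------------------------------------------------- shared boundaries
def oracle_single_linkage(edges, radius):
    """Union-find single-linkage clustering of integer positions."""
    order = np.argsort(edges, kind="stable")
    parent = list(range(len(edges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(order[:-1], order[1:]):
        if edges[b] - edges[a] <= radius:
            parent[find(b)] = find(a)
    return np.array([find(i) for i in range(len(edges))])


class TestSharedBoundaries:
    def test_identical_callers_full_support(self, rng):
        p = random_partition(rng)
        sb = shared_boundaries([p, p, p], 0)
        assert (sb.counts() == 3).all()

    def test_disjoint_sets_all_singletons(self):
        b = 10_000
        p = tc.TadPartition("c", [(1, 10 * b)], b, chrom_length_bp=100 * b)
        q = tc.TadPartition("c", [(30 * b + 1, 40 * b)], b, chrom_length_bp=100 * b)
        sb = shared_boundaries([p, q], 0)
        assert (sb.counts() == 1).all()
        assert sb.n_clusters == 4

    def test_staggered_offsets_match_oracle(self, rng):
        for _ in range(15):
            parts = [random_partition(rng, n_bins=60, max_domains=8) for _ in range(3)]
            radius = int(rng.integers(0, 4))
            sb = shared_boundaries(parts, radius)
            roots = oracle_single_linkage(sb.edges, radius)
            # same partition of edges into clusters
            _, ours = np.unique(sb.cluster_ids, return_inverse=True)
            _, theirs = np.unique(roots, return_inverse=True)
            # map cluster labels through first occurrence
            assert len(set(zip(ours, theirs))) == len(set(ours)) == len(set(theirs))
            # identical caller counts per cluster
            for cid in np.unique(ours):
                sel = ours == cid
                assert len(np.unique(sb.callers[sel])) == sb.counts()[cid]

    def test_histogram_covers_all_clusters(self, rng):
        parts = [random_partition(rng) for _ in range(4)]
        sb = shared_boundaries(parts, 2)
        assert sb.histogram().sum() == sb.n_clusters

    def test_single_partition_rejected(self, rng):
        with pytest.raises(ValidationError):
            shared_boundaries([random_partition(rng)], 1)


class TestConservationRatio:
    def test_identical_is_one(self, rng):
        p = random_partition(rng)
        assert conservation_ratio(p, p, 0) == 1.0

    def test_disjoint_is_zero(self):
        b = 10_000
        p = tc.TadPartition("c", [(1, 10 * b)], b, chrom_length_bp=50 * b)
        q = tc.TadPartition("c", [(20 * b + 1, 35 * b)], b, chrom_length_bp=50 * b)
        assert conservation_ratio(p, q, 0) == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(10):
            p = random_partition(rng, n_bins=80)
            q = random_partition(rng, n_bins=80)
            r = int(rng.integers(0, 3))
            expected = oracle_conserved_tads(p, q, r).sum() / min(
                p.n_domains, q.n_domains
            )
            assert conservation_ratio(p, q, r) == pytest.approx(expected)


class TestSizeSummary:
    def test_constant_bin_count_slopes(self):
        parts = {}
        for b in (10_000, 50_000, 100_000):
            tiles = np.arange(6)
            parts[b] = tc.TadPartition(
                "c", np.column_stack([tiles * 10 * b + 1, (tiles + 1) * 10 * b]), b
            )
        s = size_summary(parts)
        assert s.slope_bins == pytest.approx(0.0)
        assert s.slope_bp == pytest.approx(10.0)

    def test_matches_closed_form_ols(self):
        xs = np.array([10_000, 50_000, 100_000, 250_000], dtype=float)
        parts = {}
        for b in xs.astype(int):
            parts[b] = tc.TadPartition("c", [(1, 30 * b), (30 * b + 1, 50 * b)], b)
        s = size_summary(parts)
        y = np.array([25.0 * b for b in xs])
        xc, yc = xs - xs.mean(), y - y.mean()
        assert s.slope_bp == pytest.approx(float((xc * yc).sum() / (xc * xc).sum()))

    def test_single_resolution_rejected(self):
        p = tc.TadPartition("c", [(1, 100)], 100)
        with pytest.raises(ValidationError):
            size_summary({100: p})
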