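import math

import numpy as np
import pytest
from scipy import stats

from petloop.core_io import GenomicInterval, Loop, PET, PETIndex
from petloop.loopcall import (
    CandidateLoop,
    ClusterParams,
    background_windows,
    call_candidates,
    call_loops,
    dbscan2d,
    estimate_max_cut,
    estimate_resolution,
    overlap_loops,
)
from petloop.loopcall import test_candidate as assess_candidate

from conftest import canonical_labels, naive_dbscan


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def pets_from_points(points, chrom="chr1", width=50):
    out = []
    for x, y in points:
        out.append(
            PET.ordered(
                iv(int(x) - width // 2, int(x) + width - width // 2, chrom),
                iv(int(y) - width // 2, int(y) + width - width // 2, chrom),
            )
        )
    return out


class TestClusterParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ClusterParams(0, 5)
        with pytest.raises(ValueError):
            ClusterParams(100, 1)


class TestDbscan2d:
    def test_dense_blob_plus_isolated(self):
        rng = np.random.default_rng(0)
        blob = rng.integers(0, 50, size=(20, 2))
        isolated = np.array(
            [[10_000, 10_000], [20_000, 5000], [30_000, 1000],
             [40_000, 2000], [50_000, 3000]]
        )
        pts = np.vstack([blob, isolated])
        labels = dbscan2d(pts[:, 0], pts[:, 1], eps=200, min_pts=10)
        assert set(labels[:20]) == {0}
        assert all(lab == -1 for lab in labels[20:])

    def test_min_pts_above_n_all_noise(self):
        x = np.arange(5)
        labels = dbscan2d(x, x, eps=100, min_pts=10)
        assert all(lab == -1 for lab in labels)

    def test_empty(self):
        assert dbscan2d(np.array([]), np.array([]), 100, 5).size == 0

    def test_matches_naive_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(5, 400))
            x = rng.integers(0, 20_000, n)
            y = rng.integers(0, 20_000, n)
            eps = float(rng.uniform(100, 3000))
            min_pts = int(rng.integers(3, 21))
            got = canonical_labels(dbscan2d(x, y, eps, min_pts))
            want = canonical_labels(naive_dbscan(x, y, eps, min_pts))
            assert got == want

    def test_duplicate_points(self):
        x = np.zeros(12, dtype=int)
        y = np.zeros(12, dtype=int)
        labels = dbscan2d(x, y, eps=10, min_pts=10)
        assert set(labels) == {0}


class TestBackgroundWindows:
    def test_counts_and_geometry(self):
        wins = background_windows(iv(100_000, 101_000), iv(200_000, 201_000))
        # 120 shifted pairs, none lost far from diagonal / chromosome start
        assert len(wins) == 120
        assert all(wx.end <= wy.start for wx, wy in wins)

    def test_near_diagonal_windows_dropped(self):
        wins = background_windows(iv(100_000, 101_000), iv(103_000, 104_000))
        assert 0 < len(wins) < 120

    def test_near_start_windows_dropped(self):
        wins = background_windows(iv(1000, 2000), iv(50_000, 51_000))
        full = background_windows(iv(500_000, 501_000), iv(550_000, 551_000))
        assert len(wins) < len(full)


class TestTestCandidate:
    def test_zero_observation_p_one(self):
        # sparse uniform points far from the candidate
        pts = [(1000 + i * 9000, i * 9000 + 800_000) for i in range(30)]
        index = PETIndex.from_pets(pets_from_points(pts))
        cand = CandidateLoop(iv(400_000, 401_000), iv(2_000_000, 2_001_000), 0, 500)
        res = assess_candidate(index, cand)
        assert res.n_obs == 0
        assert res.p_value == 1.0

    def test_poisson_tail_matches_pmf_sum(self):
        rng = np.random.default_rng(3)
        pts = [(500_000 + rng.integers(0, 1000), 900_000 + rng.integers(0, 1000))
               for _ in range(30)]
        bg = [(rng.integers(0, 3_000_000), rng.integers(3_100_000, 6_000_000))
              for _ in range(500)]
        index = PETIndex.from_pets(pets_from_points(list(pts) + bg))
        cand = CandidateLoop(iv(500_000, 501_000), iv(900_000, 901_000), 30, 500)
        res = assess_candidate(index, cand)
        direct = 1.0 - sum(
            math.exp(-res.lam) * res.lam**i / math.factorial(i)
            for i in range(res.n_obs)
        )
        assert res.p_value == pytest.approx(direct, abs=1e-10)
        assert res.enrichment_score == pytest.approx(res.n_obs / res.lam)

    def test_adjacent_anchors_still_have_windows(self):
        # even for anchors touching at the diagonal, outward shifts exist
        wins = background_windows(iv(0, 1000), iv(1000, 2000))
        assert wins
        assert all(wx.end <= wy.start for wx, wy in wins)


class TestCallCandidates:
    def test_planted_blob_recovered(self):
        rng = np.random.default_rng(5)
        loop_pts = [
            (rng.normal(1_000_000, 150), rng.normal(1_200_000, 150))
            for _ in range(30)
        ]
        index = PETIndex.from_pets(pets_from_points(loop_pts))
        cands = call_candidates(index, [500], min_pts=10)
        assert len(cands) == 1
        c = cands[0]
        assert c.anchor_left.start <= 1_000_000 <= c.anchor_left.end
        assert c.anchor_right.start <= 1_200_000 <= c.anchor_right.end
        assert c.member_count >= 10

    def test_all_below_cut_gives_nothing(self):
        pts = [(100 + i, i + 3000) for i in range(0, 3000, 100)]
        index = PETIndex.from_pets(pets_from_points(pts))
        assert call_candidates(index, [500], 5, cut=5000) == []

    def test_empty_eps_list_errors(self):
        index = PETIndex.from_pets([])
        with pytest.raises(ValueError):
            call_candidates(index, [], 10)

    def test_diagonal_cluster_discarded(self):
        rng = np.random.default_rng(6)
        pts = [
            (rng.normal(1_000_000, 100), rng.normal(1_001_000, 100))
            for _ in range(40)
        ]
        index = PETIndex.from_pets(pets_from_points(pts))
        assert call_candidates(index, [500], 10) == []


class TestCallLoops:
    @pytest.fixture(scope="class")
    def small_index(self):
        rng = np.random.default_rng(11)
        pts = []
        for cx, cy in [(1_000_000, 1_300_000), (2_000_000, 2_500_000)]:
            pts += [
                (rng.normal(cx, 150), rng.normal(cy, 150)) for _ in range(40)
            ]
        # sparse uniform background
        for _ in range(2000):
            x = rng.uniform(0, 3_500_000)
            d = rng.uniform(10_000, 1_000_000)
            pts.append((x, x + d))
        return PETIndex.from_pets(pets_from_points(pts))

    def test_planted_loops_called_once_each(self, small_index):
        loops = call_loops(small_index, (200, 500, 1000, 2000), 10, cut=5000)
        hits = [
            lp
            for lp in loops
            if any(
                lp.anchor_left.expand(5000).overlaps(iv(c - 500, c + 500))
                for c in (1_000_000, 2_000_000)
            )
        ]
        assert len(hits) == 2  # duplicates across eps merged into one each

    def test_min_pets_monotone(self, small_index):
        n_prev = None
        for min_pets in (10, 20, 41):
            loops = call_loops(
                small_index, (200, 500, 1000, 2000), 10, cut=5000,
                min_pets=min_pets,
            )
            if n_prev is not None:
                assert len(loops) <= n_prev
            n_prev = len(loops)

    def test_loop_ids_and_sorting(self, small_index):
        loops = call_loops(small_index, (500,), 10, cut=5000)
        assert [lp.id for lp in loops] == [f"loop_{k}" for k in range(len(loops))]
        starts = [lp.anchor_left.start for lp in loops]
        assert starts == sorted(starts)


class TestEstimateResolution:
    def test_all_identical_fraction_one(self):
        pets = pets_from_points([(1000, 50_000)] * 20)
        index = PETIndex.from_pets(pets)
        res = estimate_resolution(index, [200, 1000, 5000])
        assert all(v == 1.0 for v in res.values())

    def test_all_distinct_fraction_zero(self):
        pets = pets_from_points(
            [(1000 + i * 10_000, i * 10_000 + 2_000_000) for i in range(20)]
        )
        index = PETIndex.from_pets(pets)
        assert estimate_resolution(index, [200])[200] == 0.0

    def test_mixture_matches_hash_count_oracle(self):
        rng = np.random.default_rng(8)
        pts = [
            (int(rng.integers(0, 100_000)), int(rng.integers(100_000, 300_000)))
            for _ in range(500)
        ]
        index = PETIndex.from_pets(pets_from_points(pts, width=2))
        for size in (200, 1000, 5000):
            from collections import Counter

            mids = [
                (p.left.midpoint // size, p.right.midpoint // size)
                for p in pets_from_points(pts, width=2)
            ]
            counts = Counter(mids)
            expected = sum(1 for m in mids if counts[m] >= 2) / len(mids)
            assert estimate_resolution(index, [size])[size] == pytest.approx(
                expected
            )

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            estimate_resolution(PETIndex.from_pets([]), [0])


class TestOverlapLoops:
    def loop(self, x, y, chrom="chr1"):
        return Loop(iv(x, x + 1000, chrom), iv(y, y + 1000, chrom))

    def test_identical_match(self):
        a, b = [self.loop(10_000, 100_000)], [self.loop(10_000, 100_000)]
        both, a_only, b_only = overlap_loops(a, b)
        assert len(both) == 1 and not a_only and not b_only

    def test_offset_4kb_matches_at_5kb_extension(self):
        a = [self.loop(10_000, 100_000)]
        b = [self.loop(14_000, 104_000)]
        both, a_only, b_only = overlap_loops(a, b, extension=5000)
        assert len(both) == 1
        both0, a_only0, _ = overlap_loops(a, b, extension=0)
        assert not both0 and len(a_only0) == 1

    def test_different_chromosomes_no_match(self):
        a = [self.loop(10_000, 100_000)]
        b = [self.loop(10_000, 100_000, chrom="chr2")]
        both, a_only, b_only = overlap_loops(a, b)
        assert not both and len(a_only) == 1 and len(b_only) == 1


class TestEstimateMaxCut:
    def test_pure_power_law_returns_max(self):
        rng = np.random.default_rng(1)
        d = 1000 * (10_000 / 1000) ** rng.random(50_000)  # alpha = 1
        assert estimate_max_cut(d) == int(d.max())

    def test_flattened_tail_detected(self):
        rng = np.random.default_rng(2)
        decay = 1000 * 10 ** (2 * rng.random(50_000))  # steep alpha=2-ish part
        flat = rng.uniform(100_000, 10_000_000, 50_000)  # uniform background
        cut = estimate_max_cut(np.concatenate([decay, flat]))
        assert 50_000 < cut < 10_000_000
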