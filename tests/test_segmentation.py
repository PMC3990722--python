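"""CBS statistic, permutation test, recursion, pruning: oracle + property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import acghcnv as ac
from acghcnv.segmentation import ProbeTrack, Segment


def brute_force_max_arc(x):
    """Exhaustive enumeration of all circular-arc splits (independent oracle).

    Enumerates every linear slice x[i:j] against its complement, computing
    the pooled two-sample t from slice means and sums of squares, and breaks
    ties by smallest i then j.  Splits cutting at the sequence end are the
    same circular split as cutting at 0, and are reported in the (0, i) form.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    scale = float((xc**2).sum())
    best = None
    for i in range(n):
        for j in range(i + 1, n + 1):
            if j - i == n:
                continue
            if j == n and i > 0:
                continue  # same circular split as (0, i), enumerated earlier
            inside = xc[i:j]
            outside = np.concatenate([xc[:i], xc[j:]])
            mi, mo = inside.mean(), outside.mean()
            ss = ((inside - mi) ** 2).sum() + ((outside - mo) ** 2).sum()
            if scale == 0:
                t = 0.0
            elif ss <= 1e-12 * scale:
                t = math.inf if (mi - mo) ** 2 > 1e-12 * scale else 0.0
            else:
                t = (mi - mo) / math.sqrt(ss / (n - 2) * (1 / len(inside) + 1 / len(outside)))
            if best is None or abs(t) > abs(best[2]) * (1 + 1e-12):
                best = (i, j, t)
    return best


class TestCircularMaxT:
    def test_constant_sequence_has_zero_statistic(self):
        res = ac.circular_max_t(np.full(12, 0.2))
        assert res.t == 0.0

    def test_step_sequence_splits_at_true_boundary(self):
        res = ac.circular_max_t([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        # noise-free two-level data: infinite contrast, boundary at probe 3
        assert (res.i, res.j) == (0, 3)
        assert math.isinf(res.t)

    def test_fewer_than_four_values_gives_sentinel(self):
        assert ac.circular_max_t([0.1, 0.2, 0.3]) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration_up_to_n50(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 51))
        x = rng.normal(0, 1, n)
        res = ac.circular_max_t(x)
        i, j, t = brute_force_max_arc(x)
        assert (res.i, res.j) == (i, j)
        assert abs(res.t) == pytest.approx(abs(t), rel=1e-8)

    def test_capped_search_still_finds_short_arcs(self):
        x = np.zeros(200)
        x[90:100] = 1.0
        res = ac.circular_max_t(x, max_arc=20)
        assert (res.i, res.j) == (90, 100)


class TestPermutationPvalue:
    def test_zero_statistic_gives_p_one(self, rng):
        x = rng.normal(size=30)
        assert ac.permutation_pvalue(x, 0.0, 100, seed=1) == 1.0

    def test_planted_shift_is_highly_significant(self, rng):
        x = np.concatenate([np.zeros(20), np.full(20, 1.0)]) + rng.normal(0, 0.1, 40)
        res = ac.circular_max_t(x)
        assert ac.permutation_pvalue(x, res.t, 1000, seed=2) <= 0.01

    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.normal(size=50)
        res = ac.circular_max_t(x)
        p1 = ac.permutation_pvalue(x, res.t, 200, seed=5)
        p2 = ac.permutation_pvalue(x, res.t, 200, seed=5)
        assert p1 == p2

    def test_type_i_error_near_alpha(self):
        """Fraction of flat tracks accepted at alpha stays near alpha."""
        alpha, n_rep = 0.05, 120
        hits = 0
        params = ac.SegmentationParams(alpha=alpha, n_perm=200, seed=0)
        for s in range(n_rep):
            x = np.random.default_rng(1000 + s).normal(0, 0.15, 60)
            track = ProbeTrack("chr1", np.arange(60) * 1000, x, "s")
            hits += len(ac.cbs_segment(track, ac.SegmentationParams(
                alpha=alpha, n_perm=200, seed=s))) > 1
        sd = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= alpha + 3 * sd


class TestCbsSegment:
    @staticmethod
    def track(values, sample="s1"):
        values = np.asarray(values, dtype=float)
        return ProbeTrack("chr1", np.arange(len(values)) * 1000, values, sample)

    @staticmethod
    def params(**kw):
        kw.setdefault("seed", 1)
        kw.setdefault("n_perm", 200)
        return ac.SegmentationParams(**kw)

    def test_empty_track_gives_empty_list(self):
        assert ac.cbs_segment(self.track([]), self.params()) == []

    def test_flat_track_is_one_segment(self):
        segs = ac.cbs_segment(self.track(np.zeros(50)), self.params())
        assert len(segs) == 1
        assert segs[0].num_probes == 50

    def test_noise_free_step_recovers_exact_boundary(self):
        x = np.where(np.arange(80) < 40, 0.0, 0.585)
        segs = ac.cbs_segment(self.track(x), self.params())
        assert len(segs) == 2
        assert segs[0].num_probes == 40
        assert segs[0].mean_log2 == pytest.approx(0.0)
        assert segs[1].mean_log2 == pytest.approx(0.585)

    def test_noisy_double_step_recovered_within_one_probe(self):
        rng = np.random.default_rng(3)
        x = np.zeros(120)
        x[50:70] = 0.585
        x += rng.normal(0, 0.1, 120)
        segs = ac.cbs_segment(self.track(x), self.params())
        assert len(segs) == 3
        bounds = [s.num_probes for s in segs]
        assert abs(bounds[0] - 50) <= 1
        assert abs(bounds[1] - 20) <= 1

    @given(
        st.lists(st.floats(-2, 2, allow_nan=False, width=32), min_size=8, max_size=40),
        st.integers(0, 10_000),
    )
    def test_segments_partition_the_track(self, values, seed):
        track = self.track(values)
        segs = ac.cbs_segment(track, self.params(seed=seed, n_perm=100))
        assert sum(s.num_probes for s in segs) == len(track)
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start

    def test_probe_weighted_mean_matches_track_mean(self, rng):
        x = rng.normal(0, 0.3, 90)
        x[30:60] += 1.0
        track = self.track(x)
        segs = ac.cbs_segment(track, self.params())
        weighted = sum(s.mean_log2 * s.num_probes for s in segs) / len(track)
        assert weighted == pytest.approx(float(x.mean()), abs=1e-12)


class TestPruneSegments:
    @staticmethod
    def seg(start, n, mean):
        return Segment("chr1", start, start + n * 1000, n, mean, "s1")

    def test_zero_threshold_is_identity(self):
        segs = [self.seg(0, 10, 0.0), self.seg(10_000, 10, 0.05)]
        assert ac.prune_segments(segs, 0.0, robust_sd=0.1) == segs

    def test_equal_means_are_merged(self):
        segs = [self.seg(0, 10, 0.2), self.seg(10_000, 5, 0.2)]
        merged = ac.prune_segments(segs, 1.0, robust_sd=0.1)
        assert len(merged) == 1
        assert merged[0].num_probes == 15
        assert merged[0].mean_log2 == pytest.approx(0.2)

    def test_idempotent(self):
        segs = [
            self.seg(0, 10, 0.0),
            self.seg(10_000, 4, 0.04),
            self.seg(14_000, 8, 0.7),
        ]
        once = ac.prune_segments(segs, 1.0, robust_sd=0.1)
        twice = ac.prune_segments(once, 1.0, robust_sd=0.1)
        assert once == twice

    def test_distinct_levels_not_merged(self):
        segs = [self.seg(0, 10, 0.0), self.seg(10_000, 10, 0.585)]
        assert len(ac.prune_segments(segs, 1.0, robust_sd=0.15)) == 2

    def test_merged_mean_is_probe_weighted(self):
        segs = [self.seg(0, 30, 0.0), self.seg(30_000, 10, 0.08)]
        merged = ac.prune_segments(segs, 1.0, robust_sd=0.15)
        assert merged[0].mean_log2 == pytest.approx((30 * 0.0 + 10 * 0.08) / 40)


class TestSegmentCohort:
    def test_deterministic_and_partitions_every_track(self, small_cohort):
        params = ac.SegmentationParams(n_perm=100, max_arc=32, seed=2)
        seg1 = ac.segment_cohort(small_cohort.probes, params)
        seg2 = ac.segment_cohort(small_cohort.probes, params)
        assert seg1.equals(seg2)
        n_probes = len(small_cohort.probes)
        for sample in small_cohort.truth.samples:
            per_sample = seg1[seg1["sample"] == sample]["num_probes"].sum()
            assert per_sample == n_probes

    def test_robust_sd_tracks_probe_noise(self, rng):
        x = rng.normal(0, 0.15, 2000)
        x[100:150] += 1.0  # robust estimate must ignore the shift
        assert ac.robust_track_sd(x) == pytest.approx(0.15, rel=0.1)
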