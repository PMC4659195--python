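"""Intersection-union analysis, proportion testing, aggregation, recovered
segments and their characterisation — each against a brute-force oracle."""

import numpy as np
import pytest
from scipy import stats

from rexome.concordance import (
    SegmentSet,
    aggregate_profiles,
    intersect_segments_exons,
    iut,
    recovered_mask,
    segment_length_distribution,
    segments_from_mask,
    two_proportion_test,
)
from rexome.core import DepthProfile, TargetRegions
from rexome.coverage import CoverageMask, coverage_mask, mean_target_depth


def _mask(values, targets=None, t=20):
    values = np.asarray(values, dtype=bool)
    if targets is None:
        targets = TargetRegions([("chr1", 0, values.size)])
    return CoverageMask(targets, t, values)


def brute_force_venn(m1, m2, m3):
    venn = {k: 0 for k in ("100", "010", "001", "110", "101", "011", "111")}
    for a, b, c in zip(m1, m2, m3):
        key = f"{int(a)}{int(b)}{int(c)}"
        if key != "000":
            venn[key] += 1
    return venn


class TestIUT:
    def test_identical_masks_no_variability(self, rng):
        v = rng.random(200) < 0.5
        res = iut([_mask(v), _mask(v), _mask(v)])
        assert res.variable_count == 0
        assert res.intersection_count == res.union_count == int(v.sum())

    def test_venn_matches_per_base_enumeration(self, rng):
        for _ in range(5):
            t = TargetRegions([("chr1", 0, 100)])
            vs = [rng.random(100) < 0.6 for _ in range(3)]
            res = iut([_mask(v, t) for v in vs])
            assert res.venn == brute_force_venn(*vs)

    def test_conservation_identities(self, rng):
        t = TargetRegions([("chr1", 0, 1000)])
        vs = [rng.random(1000) < p for p in (0.9, 0.7, 0.5)]
        res = iut([_mask(v, t) for v in vs])
        assert sum(res.venn.values()) == res.union_count
        assert res.intersection_count + res.variable_count == res.union_count
        assert res.union_count + res.uncovered_count == res.n_total
        union = vs[0] | vs[1] | vs[2]
        inter = vs[0] & vs[1] & vs[2]
        assert res.union_count == int(union.sum())
        assert res.intersection_count == int(inter.sum())

    def test_mismatched_inputs_rejected(self, rng):
        v = rng.random(50) < 0.5
        with pytest.raises(ValueError, match="thresholds"):
            iut([_mask(v, t=20), _mask(v, t=20), _mask(v, t=10)])
        other = TargetRegions([("chr2", 0, 50)])
        with pytest.raises(ValueError, match="target spaces"):
            iut([_mask(v), _mask(v), _mask(v, other)])


def hand_chi2_2x2(x1, n1, x2, n2, continuity):
    """Independent oracle: the textbook 2x2 chi-square with clipped Yates
    correction, written directly from the contingency-table formula."""
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    n = n1 + n2
    adj = min(0.5 * n, abs(a * d - b * c)) if continuity else 0.0
    num = n * (abs(a * d - b * c) - adj) ** 2
    den = n1 * n2 * (a + c) * (b + d)
    chi2 = num / den
    return chi2, stats.chi2.sf(chi2, 1)


class TestTwoProportionTest:
    def test_equal_proportions(self):
        res = two_proportion_test(5, 10, 50, 100, continuity=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_against_hand_formula(self):
        res = two_proportion_test(5, 10, 9, 10, continuity=True)
        chi2, p = hand_chi2_2x2(5, 10, 9, 10, True)
        assert res.statistic == pytest.approx(chi2, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_symmetry(self):
        a = two_proportion_test(7, 20, 15, 30)
        b = two_proportion_test(15, 30, 7, 20)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-14)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_test(1, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_test(3, 2, 1, 2)

    def test_degenerate_margins(self):
        res = two_proportion_test(0, 10, 0, 20)
        assert res.p_value == 1.0


class TestAggregate:
    def test_sum_of_depths(self):
        t = TargetRegions([("chr1", 0, 1)])
        profs = [DepthProfile(t, [d], "S1", f"R{i}") for i, d in enumerate([10, 20, 30])]
        assert aggregate_profiles(profs).depth[0] == 60

    def test_identity_on_single_profile(self, rng):
        t = TargetRegions([("chr1", 0, 30)])
        p = DepthProfile(t, rng.integers(0, 9, 30), "S1", "R1")
        agg = aggregate_profiles([p])
        assert np.array_equal(agg.depth, p.depth)
        assert agg.replicate_id == "aggregate"

    def test_mean_depth_is_linear(self, rng):
        t = TargetRegions([("chr1", 0, 100)])
        profs = [DepthProfile(t, rng.integers(0, 50, 100), "S1", f"R{i}")
                 for i in range(3)]
        assert mean_target_depth(aggregate_profiles(profs)) == pytest.approx(
            sum(mean_target_depth(p) for p in profs)
        )

    def test_mixed_samples_rejected(self):
        t = TargetRegions([("chr1", 0, 5)])
        with pytest.raises(ValueError, match="samples"):
            aggregate_profiles(
                [DepthProfile(t, [1] * 5, "S1", "R1"),
                 DepthProfile(t, [1] * 5, "S2", "R1")]
            )


class TestRecoveredMask:
    def test_near_threshold_base_recovered(self):
        t = TargetRegions([("chr1", 0, 1)])
        reps = [DepthProfile(t, [19], "S1", f"R{i}") for i in range(3)]
        agg = aggregate_profiles(reps)
        rec = recovered_mask(
            coverage_mask(agg, 20), [coverage_mask(p, 20) for p in reps]
        )
        assert rec.values[0]  # 19+19+19 = 57 >= 20 but no replicate reaches it

    def test_base_in_replicate_intersection_not_recovered(self):
        t = TargetRegions([("chr1", 0, 1)])
        reps = [DepthProfile(t, [25], "S1", f"R{i}") for i in range(3)]
        rec = recovered_mask(
            coverage_mask(aggregate_profiles(reps), 20),
            [coverage_mask(p, 20) for p in reps],
        )
        assert not rec.values[0]

    def test_matches_set_difference(self, rng):
        t = TargetRegions([("chr1", 0, 500)])
        reps = [DepthProfile(t, rng.integers(0, 40, 500), "S1", f"R{i}")
                for i in range(3)]
        agg = aggregate_profiles(reps)
        rep_masks = [coverage_mask(p, 20) for p in reps]
        rec = recovered_mask(coverage_mask(agg, 20), rep_masks)
        brute = {
            i for i in range(500)
            if agg.depth[i] >= 20 and not all(p.depth[i] >= 20 for p in reps)
        }
        assert set(np.flatnonzero(rec.values)) == brute
        # recovered within aggregate mask, disjoint from the intersection
        inter = np.logical_and.reduce([m.values for m in rep_masks])
        assert not (rec.values & ~coverage_mask(agg, 20).values).any()
        assert not (rec.values & inter).any()


class TestSegments:
    def test_simple_runs(self):
        t = TargetRegions([("chr1", 0, 4)])
        segs = segments_from_mask(CoverageMask(t, 20, [True, True, False, True]))
        assert list(segs) == [("chr1", 0, 2), ("chr1", 3, 4)]
        assert list(segs.lengths) == [2, 1]

    def test_all_false_empty(self):
        t = TargetRegions([("chr1", 0, 10)])
        segs = segments_from_mask(CoverageMask(t, 20, np.zeros(10, bool)))
        assert segs.n_segments == 0

    def test_runs_do_not_span_target_gaps(self):
        t = TargetRegions([("chr1", 0, 5), ("chr1", 10, 15)])
        segs = segments_from_mask(CoverageMask(t, 20, np.ones(10, bool)))
        assert list(segs) == [("chr1", 0, 5), ("chr1", 10, 15)]

    def test_matches_brute_force_rle(self, rng):
        t = TargetRegions([("chr1", 0, 40), ("chr1", 60, 110), ("chr2", 0, 30)])
        v = rng.random(t.total_bases) < 0.5
        segs = segments_from_mask(CoverageMask(t, 20, v))
        # oracle: per-base scan over genomic coordinates
        covered = set()
        chroms, pos = t.flat_to_genomic(np.flatnonzero(v))
        for c, p in zip(chroms, pos):
            covered.add((c, int(p)))
        brute = []
        for chrom, s, e in t.intervals:
            run = None
            for p in range(s, e):
                if (chrom, p) in covered:
                    run = [chrom, p, p + 1] if run is None else [chrom, run[1], p + 1]
                else:
                    if run:
                        brute.append(tuple(run))
                    run = None
            if run:
                brute.append(tuple(run))
        assert list(segs) == brute
        assert segs.total_bases == int(v.sum())


class TestSegmentLengthDistribution:
    @staticmethod
    def _segs(lengths):
        lengths = np.asarray(lengths, dtype=np.int64)
        starts = np.cumsum(np.concatenate([[0], lengths[:-1] + 5]))
        return SegmentSet(
            np.array(["chr1"] * lengths.size, dtype=object),
            starts, starts + lengths,
        )

    def test_frequency_tally(self):
        freq, _, mean_len = segment_length_distribution(
            self._segs([1, 1, 1, 1, 2, 2])
        )
        assert freq == {1: 4, 2: 2}
        assert mean_len == pytest.approx(8 / 6)
        assert freq[1] == 4  # singleton count is the frequency at length 1

    def test_exact_power_law_slope(self):
        # freq(L) = 256 / L^2 over L in {1, 2, 4, 8, 16}: slope exactly -2
        lengths = []
        for L in (1, 2, 4, 8, 16):
            lengths += [L] * (256 // L**2)
        _, fit, _ = segment_length_distribution(self._segs(lengths))
        assert fit.slope == pytest.approx(-2.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_single_length_no_slope(self):
        freq, fit, _ = segment_length_distribution(self._segs([3, 3]))
        assert fit is None and freq == {3: 2}


class TestExonIntersection:
    def test_simple_overlap(self):
        segs = SegmentSet(np.array(["chr1"], dtype=object),
                          np.array([0]), np.array([100]))
        exons = TargetRegions([("chr1", 50, 60)])
        assert intersect_segments_exons(segs, exons, min_len=50) == (1, 10)

    def test_min_len_strictly_greater(self):
        segs = SegmentSet(np.array(["chr1"], dtype=object),
                          np.array([0]), np.array([50]))
        exons = TargetRegions([("chr1", 0, 100)])
        assert intersect_segments_exons(segs, exons, min_len=50) == (0, 0)
        assert intersect_segments_exons(segs, exons, min_len=49) == (1, 50)

    def test_matches_per_base_intersection(self, rng):
        # oracle: explicit base sets
        seg_ivs = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(1, 30))
            L = int(rng.integers(1, 120))
            seg_ivs.append(("chr1", pos, pos + L))
            pos += L
        segs = SegmentSet(
            np.array([c for c, _, _ in seg_ivs], dtype=object),
            np.array([s for _, s, _ in seg_ivs]),
            np.array([e for _, _, e in seg_ivs]),
        )
        exon_ivs = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(1, 50))
            L = int(rng.integers(1, 80))
            exon_ivs.append(("chr1", pos, pos + L))
            pos += L
        exons = TargetRegions(exon_ivs)
        exon_bases = {p for _, s, e in exon_ivs for p in range(s, e)}
        n_expected, bases_expected = 0, 0
        for c, s, e in seg_ivs:
            if e - s <= 50:
                continue
            ov = len(set(range(s, e)) & exon_bases)
            if ov:
                n_expected += 1
                bases_expected += ov
        assert intersect_segments_exons(segs, exons, min_len=50) == (
            n_expected, bases_expected,
        )
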