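"""Replicate concordance: intersection-union analysis of coverage masks,
aggregation, recovered-segment extraction and characterisation.

The intersection-union test (IUT) asks, for a set of technical-replicate
capture libraries of one individual, what fraction of targeted bases reach a
depth threshold in *all* replicates (intersection) versus in *at least one*
(union).  The difference — the "variable" fraction — measures stochastic
capture variability.  Aggregating replicates (summing per-base depth, as a
BAM merge would) recovers bases that individually missed the threshold;
those recovered bases form segments whose length distribution and overlap
with coding exons are characterised here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DepthProfile, TargetRegions
from .coverage import CoverageMask

#: order of the 7 non-empty Venn regions of (R1, R2, R3); "110" means
#: covered in R1 and R2 but not R3
VENN_KEYS = ("100", "010", "001", "110", "101", "011", "111")


@dataclass
class IUTResult:
    """Venn / intersection / union counts for replicate coverage masks."""

    threshold: int
    n_total: int
    venn: dict[str, int]

    def __post_init__(self) -> None:
        # conservation identities hold by construction; assert anyway
        assert sum(self.venn.values()) == self.union_count
        assert self.variable_count >= 0

    @property
    def intersection_count(self) -> int:
        return self.venn["111"]

    @property
    def union_count(self) -> int:
        return sum(self.venn.values())

    @property
    def variable_count(self) -> int:
        return self.union_count - self.intersection_count

    @property
    def uncovered_count(self) -> int:
        return self.n_total - self.union_count

    @property
    def intersection_pct(self) -> float:
        return 100.0 * self.intersection_count / self.n_total

    @property
    def variable_pct(self) -> float:
        return 100.0 * self.variable_count / self.n_total

    @property
    def uncovered_pct(self) -> float:
        return 100.0 * self.uncovered_count / self.n_total


def iut(masks: list[CoverageMask]) -> IUTResult:
    """Intersection-union analysis of three replicate coverage masks.

    Venn counts are computed by per-base membership classification in a
    single pass, so the conservation identities (sum of regions = union,
    intersection + variable = union) hold by construction.
    """
    if len(masks) != 3:
        raise ValueError(f"IUT is defined for 3 replicate masks, got {len(masks)}")
    t = masks[0].threshold
    targets = masks[0].targets
    for m in masks[1:]:
        if m.targets != targets:
            raise ValueError("masks cover different target spaces")
        if m.threshold != t:
            raise ValueError("masks computed at different thresholds")
    code = (
        masks[0].values.astype(np.int8) * 4
        + masks[1].values.astype(np.int8) * 2
        + masks[2].values.astype(np.int8)
    )
    counts = np.bincount(code, minlength=8)
    venn = {key: int(counts[int(key, 2)]) for key in VENN_KEYS}
    return IUTResult(threshold=t, n_total=targets.total_bases, venn=venn)


@dataclass
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    statistic: float
    p_value: float
    continuity: bool


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> ProportionTestResult:
    """Chi-square test that two binomial proportions are equal.

    Matches R's ``prop.test`` for two groups: a 2x2 chi-square with the
    Yates continuity correction when *continuity* is set; two-sided p-value.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # a zero column margin means the two proportions are identical
        stat, p = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=continuity)
        stat, p = float(res.statistic), float(res.pvalue)
    return ProportionTestResult(x1, n1, x2, n2, stat, p, continuity)


def aggregate_profiles(profiles: list[DepthProfile]) -> DepthProfile:
    """Per-base sum of replicate profiles (the depth-level BAM merge)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    targets = profiles[0].targets
    sample = profiles[0].sample_id
    for p in profiles[1:]:
        if p.targets != targets:
            raise ValueError("profiles cover different target spaces")
        if p.sample_id != sample:
            raise ValueError(
                f"cannot aggregate across samples ({p.sample_id!r} != {sample!r})"
            )
    depth = np.sum([p.depth for p in profiles], axis=0)
    return DepthProfile(targets, depth, sample, "aggregate")


def recovered_mask(
    aggregate_mask: CoverageMask, replicate_masks: list[CoverageMask]
) -> CoverageMask:
    """Bases reaching the threshold in the aggregate but not in every replicate.

    The baseline is the replicate *intersection*: a base is recovered iff
    the aggregate covers it and at least one replicate does not.
    """
    t = aggregate_mask.threshold
    targets = aggregate_mask.targets
    for m in replicate_masks:
        if m.threshold != t:
            raise ValueError("replicate mask threshold differs from aggregate")
        if m.targets != targets:
            raise ValueError("masks cover different target spaces")
    inter = np.logical_and.reduce([m.values for m in replicate_masks])
    return CoverageMask(targets, t, aggregate_mask.values & ~inter)


@dataclass
class SegmentSet:
    """Maximal runs of true bases in a mask, as genomic intervals."""

    chroms: np.ndarray   # object array of chrom names, one per segment
    starts: np.ndarray   # 0-based
    ends: np.ndarray     # half-open

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    def __iter__(self):
        return iter(zip(self.chroms, self.starts, self.ends))


def segments_from_mask(mask: CoverageMask) -> SegmentSet:
    """Maximal consecutive runs of covered bases; runs never span the gap
    between two target intervals."""
    t = mask.targets
    idx = np.flatnonzero(mask.values)
    if idx.size == 0:
        e = np.array([], dtype=np.int64)
        return SegmentSet(np.array([], dtype=object), e, e.copy())
    iv = t.interval_index(idx)
    brk = np.flatnonzero((np.diff(idx) != 1) | (np.diff(iv) != 0))
    first = idx[np.concatenate([[0], brk + 1])]
    last = idx[np.concatenate([brk, [idx.size - 1]])]
    chroms, starts = t.flat_to_genomic(first)
    _, last_pos = t.flat_to_genomic(last)
    return SegmentSet(chroms, starts, last_pos + 1)


@dataclass
class PowerLawSummary:
    """Log-log least-squares slope of a segment-length frequency spectrum."""

    slope: float
    intercept: float
    r_squared: float
    n_lengths: int


def segment_length_distribution(
    segments: SegmentSet,
) -> tuple[dict[int, int], PowerLawSummary | None, float]:
    """Frequency of segment lengths, a log-log power-law fit, mean length.

    The slope is an ordinary least-squares fit of log10(frequency) on
    log10(length) over lengths with nonzero frequency; it is ``None`` when
    fewer than two distinct lengths exist.
    """
    lengths = segments.lengths
    if lengths.size == 0:
        return {}, None, float("nan")
    vals, counts = np.unique(lengths, return_counts=True)
    freq = {int(v): int(c) for v, c in zip(vals, counts)}
    mean_len = float(lengths.mean())
    if len(vals) < 2:
        return freq, None, mean_len
    lx, ly = np.log10(vals), np.log10(counts)
    res = stats.linregress(lx, ly)
    fit = PowerLawSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_lengths=len(vals),
    )
    return freq, fit, mean_len


def intersect_segments_exons(
    segments: SegmentSet, exons: TargetRegions, min_len: int = 50
) -> tuple[int, int]:
    """Overlap of long recovered segments with coding exons.

    Only segments strictly longer than *min_len* are considered.  Returns
    ``(n_overlapping_segments, overlapped_coding_bases)``: a segment counts
    once if it overlaps at least one exon base, and the base total is the
    sum of per-segment overlaps.
    """
    keep = segments.lengths > min_len
    n_regions = 0
    total = 0
    # prefix sums of exon lengths per chrom for O(log n) overlap queries
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sl in exons._chrom_slice.items():
        s, e = exons.starts[sl], exons.ends[sl]
        per_chrom[chrom] = (s, e, np.concatenate([[0], np.cumsum(e - s)]))
    for chrom, seg_s, seg_e in zip(
        segments.chroms[keep], segments.starts[keep], segments.ends[keep]
    ):
        info = per_chrom.get(str(chrom))
        if info is None:
            continue
        ex_s, ex_e, cum = info
        i = np.searchsorted(ex_e, seg_s, side="right")
        j = np.searchsorted(ex_s, seg_e, side="left")
        if i >= j:
            continue
        ov = cum[j] - cum[i]
        ov -= max(0, seg_s - ex_s[i])
        ov -= max(0, ex_e[j - 1] - seg_e)
        if ov > 0:
            n_regions += 1
            total += int(ov)
    return n_regions, total
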