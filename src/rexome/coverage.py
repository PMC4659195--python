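"""Per-replicate and aggregate coverage summaries.

Covers the standard exome QC quantities: mean target depth, percent of
targeted bases at or above depth thresholds, per-base depth densities, and a
loess trend (span 0.75 with a pointwise 95% band) of coverage versus total
aligned input, used to visualise coverage saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import DepthProfile, TargetRegions

DEFAULT_THRESHOLDS = (1, 10, 20)


@dataclass
class CoverageMask:
    """Boolean per-target-base mask: depth >= threshold."""

    targets: TargetRegions
    threshold: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (self.targets.total_bases,):
            raise ValueError("mask length does not match target space")
        if self.threshold < 1:
            raise ValueError("coverage threshold must be >= 1")

    @property
    def covered_count(self) -> int:
        return int(self.values.sum())

    @property
    def covered_pct(self) -> float:
        return 100.0 * self.covered_count / self.targets.total_bases


def coverage_mask(profile: DepthProfile, t: int) -> CoverageMask:
    """Mask of target bases sequenced to at least *t*-fold depth (inclusive)."""
    if t < 1:
        raise ValueError(f"coverage threshold must be >= 1, got {t}")
    return CoverageMask(profile.targets, int(t), profile.depth >= t)


def mean_target_depth(profile: DepthProfile) -> float:
    """Mean per-base depth over the full target space (zeros included)."""
    if profile.targets.total_bases == 0:
        raise ValueError("empty target space")
    return float(profile.depth.sum() / profile.targets.total_bases)


def percent_target_at(profile: DepthProfile, thresholds=DEFAULT_THRESHOLDS) -> dict[int, float]:
    """Percent of targeted bases at >= t for each threshold (unrounded)."""
    return {int(t): coverage_mask(profile, t).covered_pct for t in thresholds}


def summarize_percentages(values) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of replicate percentages, 1 decimal.

    The dispersion is the sample standard deviation of the replicate values
    even where summary tables label such a column "SE".
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("dispersion undefined for fewer than 2 replicates")
    return round(float(values.mean()), 1), round(float(values.std(ddof=1)), 1)


@dataclass
class CoverageSummary:
    """Table-style coverage summary for one individual's replicate group."""

    sample_id: str
    thresholds: tuple[int, ...]
    replicate_ids: list[str]
    mean_depths: list[float]                    # per replicate, x units
    replicate_pct: dict[int, list[float]]       # threshold -> per-replicate %
    mean_sd: dict[int, tuple[float, float]]     # threshold -> (mean, SD)


def replicate_summary(
    profiles: list[DepthProfile], thresholds=DEFAULT_THRESHOLDS
) -> CoverageSummary:
    """Per-threshold replicate percentages with mean and sample SD.

    Requires at least two replicate profiles over the same target space.
    """
    if len(profiles) < 2:
        raise ValueError("replicate dispersion undefined for < 2 replicates")
    targets = profiles[0].targets
    sample = profiles[0].sample_id
    for p in profiles[1:]:
        if p.targets != targets:
            raise ValueError("replicate profiles cover different target spaces")
    thresholds = tuple(int(t) for t in thresholds)
    pct = {t: [] for t in thresholds}
    for p in profiles:
        for t, v in percent_target_at(p, thresholds).items():
            pct[t].append(round(v, 1))
    return CoverageSummary(
        sample_id=sample,
        thresholds=thresholds,
        replicate_ids=[p.replicate_id for p in profiles],
        mean_depths=[round(mean_target_depth(p), 1) for p in profiles],
        replicate_pct=pct,
        mean_sd={t: summarize_percentages(v) for t, v in pct.items()},
    )


def depth_density(profile: DepthProfile) -> np.ndarray:
    """Normalised per-base depth histogram; index = depth, masses sum to 1."""
    if profile.targets.total_bases == 0:
        raise ValueError("empty profile")
    counts = np.bincount(profile.depth)
    return counts / counts.sum()


@dataclass
class LoessFit:
    """A loess trend with a pointwise 95% confidence band.

    ``fitted`` is defined at every observed ``x`` (sorted); the band is
    ``fitted +/- 1.96 * SE`` with SE estimated by a residual bootstrap, so the
    band always contains the fitted line.
    """

    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float
    method: str = "statsmodels lowess (locally weighted linear regression)"


def loess_trend(
    x, y, span: float = 0.75, n_boot: int = 200, random_state: int = 0
) -> LoessFit:
    """Loess fit of y against x (default span 0.75) with a 95% band.

    Used for percent-target-covered versus total aligned gigabases
    (coverage saturation).  Requires at least 4 points; duplicate x values
    are allowed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 4:
        raise ValueError(f"loess needs >= 4 points, got {x.size}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = sm.nonparametric.lowess(ys, xs, frac=span, return_sorted=False)
    resid = ys - fitted
    rng = np.random.default_rng(random_state)
    boots = np.empty((n_boot, xs.size))
    for b in range(n_boot):
        yb = fitted + rng.choice(resid, size=resid.size, replace=True)
        boots[b] = sm.nonparametric.lowess(yb, xs, frac=span, return_sorted=False)
    se = boots.std(axis=0, ddof=1)
    return LoessFit(
        x=xs, y=ys, fitted=fitted,
        lower=fitted - 1.96 * se, upper=fitted + 1.96 * se,
        span=float(span),
    )
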