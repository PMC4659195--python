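"""Genotype calling from allele counts and depth-binned replicate discordance.

The caller is a three-genotype binomial Bayes classifier: given Q20-filtered
ref/alt base counts at a site, the likelihood of the alt count is binomial
with alt-allele probability eps (hom_ref), 0.5 (het) or 1-eps (hom_alt),
where eps is the per-base miscall rate.  The call is the posterior argmax and
its quality is the log10 posterior ratio of the best to the second-best
genotype; calls below the quality threshold or the minimum depth are no_call.

Discordance analysis bins every targeted position by the minimum depth
across an individual's replicates (10-19x, 20-29x, >=30x; positions below
10x are excluded) and counts sites where the replicate genotype calls
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENOTYPE_STATES, GT_COLUMNS, NO_CALL, DepthProfile, TargetRegions

#: (label, low, high) with inclusive bounds; high None = unbounded
DEPTH_BINS = (("10-19x", 10, 19), ("20-29x", 20, 29), (">=30x", 30, None))
BIN_LABELS = tuple(b[0] for b in DEPTH_BINS)
MIN_BIN_DEPTH = DEPTH_BINS[0][1]


@dataclass
class GenotypeCall:
    genotype: str
    quality: float
    depth: int


def _log10_likelihoods(ref: np.ndarray, alt: np.ndarray, eps: float) -> np.ndarray:
    """(n, 3) log10 binomial likelihoods for (hom_ref, het, hom_alt).

    The binomial coefficient is genotype-independent and omitted.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    ll = np.empty((ref.size, 3))
    ll[:, 0] = ref * np.log10(1 - eps) + alt * np.log10(eps)
    ll[:, 1] = (ref + alt) * np.log10(0.5)
    ll[:, 2] = ref * np.log10(eps) + alt * np.log10(1 - eps)
    return ll


def call_genotypes(
    ref_counts,
    alt_counts,
    base_error_rate: float = 0.01,
    priors=None,
    min_call_depth: int = 10,
    quality_threshold: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Bayes caller; returns (genotype tokens, qualities)."""
    if not 0 < base_error_rate < 0.5:
        raise ValueError(
            f"base_error_rate must be in (0, 0.5), got {base_error_rate}"
        )
    ref = np.atleast_1d(np.asarray(ref_counts, dtype=np.int64))
    alt = np.atleast_1d(np.asarray(alt_counts, dtype=np.int64))
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("negative allele counts")
    if priors is None:
        priors = np.full(3, 1.0 / 3.0)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (3,) or (priors <= 0).any():
        raise ValueError("priors must be 3 positive weights")
    post = _log10_likelihoods(ref, alt, base_error_rate) + np.log10(priors)
    order = np.argsort(post, axis=1)
    best = order[:, 2]
    quality = post[np.arange(len(post)), best] - post[np.arange(len(post)), order[:, 1]]
    genotype = np.array(GENOTYPE_STATES, dtype=object)[best]
    depth = ref + alt
    genotype[(depth < min_call_depth) | (quality < quality_threshold)] = NO_CALL
    return genotype, quality


def call_genotype(
    ref_count: int,
    alt_count: int,
    base_error_rate: float = 0.01,
    priors=None,
    min_call_depth: int = 10,
    quality_threshold: float = 1.0,
) -> GenotypeCall:
    """Call a single site; see :func:`call_genotypes`."""
    g, q = call_genotypes(
        [ref_count], [alt_count], base_error_rate, priors,
        min_call_depth, quality_threshold,
    )
    return GenotypeCall(str(g[0]), float(q[0]), int(ref_count + alt_count))


def call_table(
    counts: pd.DataFrame,
    base_error_rate: float = 0.01,
    priors=None,
    min_call_depth: int = 10,
    quality_threshold: float = 1.0,
) -> pd.DataFrame:
    """Call genotypes for an allele-count table.

    *counts* needs columns chrom, pos, ref, alt, sample, replicate,
    ref_count, alt_count; the result is a genotype table (GT_COLUMNS).
    """
    g, q = call_genotypes(
        counts["ref_count"].to_numpy(), counts["alt_count"].to_numpy(),
        base_error_rate, priors, min_call_depth, quality_threshold,
    )
    out = counts.loc[:, ["chrom", "pos", "ref", "alt", "sample", "replicate"]].copy()
    out["genotype"] = g
    out["depth"] = counts["ref_count"].to_numpy() + counts["alt_count"].to_numpy()
    out["quality"] = np.round(q, 4)
    return out.loc[:, list(GT_COLUMNS)]


# ----------------------------------------------------------------------
# Depth binning and discordance
# ----------------------------------------------------------------------

def bin_for_depth(depth) -> np.ndarray:
    """Bin index (0, 1, 2) per depth value; -1 for depth below 10."""
    depth = np.asarray(depth, dtype=np.int64)
    out = np.full(depth.shape, -1, dtype=np.int8)
    for i, (_, lo, hi) in enumerate(DEPTH_BINS):
        m = depth >= lo
        if hi is not None:
            m &= depth <= hi
        out[m] = i
    return out


def bin_positions(profiles: list[DepthProfile], stat: str = "min") -> np.ndarray:
    """Assign every target base of one individual to a depth bin.

    The binning depth is the minimum (default) or mean depth across the
    individual's replicates; positions whose binning depth is below 10 get
    bin -1 (excluded).
    """
    if len(profiles) < 2:
        raise ValueError("binning needs >= 2 replicate profiles")
    targets = profiles[0].targets
    for p in profiles[1:]:
        if p.targets != targets:
            raise ValueError("profiles cover different target spaces")
    stack = np.stack([p.depth for p in profiles])
    if stat == "min":
        d = stack.min(axis=0)
    elif stat == "mean":
        d = np.floor(stack.mean(axis=0)).astype(np.int64)
    else:
        raise ValueError(f"unknown bin stat {stat!r}")
    return bin_for_depth(d)


@dataclass
class DiscordanceSummary:
    """Per-bin replicate genotype discordance for one individual."""

    sample_id: str
    evaluated: dict[str, int]          # bin label -> positions evaluated
    discordant: dict[str, int]         # bin label -> discordant sites
    discordant_sites: pd.DataFrame     # chrom, pos, bin, per-replicate genotypes

    def rate(self, label: str) -> float:
        n = self.evaluated[label]
        return self.discordant[label] / n if n else 0.0

    def rates_per_million(self) -> dict[str, float]:
        """Rates in units of 1e-6, one decimal (reporting convention)."""
        return {b: round(1e6 * self.rate(b), 1) for b in BIN_LABELS}


def discordance(
    calls: pd.DataFrame,
    bin_assign: np.ndarray,
    targets: TargetRegions,
) -> DiscordanceSummary:
    """Depth-binned genotype discordance between technical replicates.

    *calls* holds one individual's per-replicate genotype calls at candidate
    variant sites; positions absent from the table are implicitly concordant
    (uniformly called reference).  Sites where any replicate is no_call are
    excluded from both numerator and denominator.  The denominator per bin
    is the number of binned target positions minus the excluded sites.
    """
    if np.asarray(bin_assign).shape != (targets.total_bases,):
        raise ValueError("bin assignment does not match target space")
    samples = calls["sample"].unique()
    if len(samples) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(samples)}")
    sample = samples[0] if len(samples) else ""

    bin_counts = {
        lab: int((bin_assign == i).sum()) for i, (lab, _, _) in enumerate(DEPTH_BINS)
    }
    flat = targets.locate_table(calls["chrom"].to_numpy(), calls["pos"].to_numpy())
    if (flat < 0).any():
        raise ValueError("genotype call at a position outside the target space")
    wide = (
        calls.assign(_flat=flat)
        .pivot_table(
            index="_flat", columns="replicate", values="genotype", aggfunc="first"
        )
        .fillna("hom_ref")
    )
    site_bins = np.asarray(bin_assign)[wide.index.to_numpy()]
    gt = wide.to_numpy(dtype=object)
    any_nocall = (gt == NO_CALL).any(axis=1)
    disagree = ~(gt == gt[:, :1]).all(axis=1)

    evaluated = dict(bin_counts)
    discordant = {lab: 0 for lab in BIN_LABELS}
    rows = []
    for k, lab in enumerate(BIN_LABELS):
        in_bin = site_bins == k
        evaluated[lab] -= int((in_bin & any_nocall).sum())
        hit = in_bin & ~any_nocall & disagree
        discordant[lab] = int(hit.sum())
        for fi, genos in zip(wide.index.to_numpy()[hit], gt[hit]):
            chroms, pos = targets.flat_to_genomic([fi])
            rows.append(
                {"chrom": chroms[0], "pos": int(pos[0]), "bin": lab,
                 **dict(zip(wide.columns, genos))}
            )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "bin", *wide.columns])
    return DiscordanceSummary(sample, evaluated, discordant, sites)


@dataclass
class DiscordanceClassification:
    """Discordant sites labelled by their truth genotype (the role Sanger
    re-sequencing played for real data)."""

    tallies: dict[str, int]            # truth genotype -> count
    unvalidated: int
    percentages: dict[str, float]      # over classified sites, 1 decimal
    missed_het: int                    # truth het, >=1 replicate non-het
    false_het: int                     # truth hom, >=1 replicate het
    missed_het_rate: float             # per evaluated position, contributing bins
    denominator: int


def classify_discordances(
    summary: DiscordanceSummary, truth: pd.DataFrame
) -> DiscordanceClassification:
    """Classify discordant sites against truth genotypes.

    *truth* needs columns chrom, pos, genotype for the same individual.
    The missed-het rate denominator is the positions evaluated in the bins
    that contributed at least one discordant site.
    """
    sites = summary.discordant_sites
    rep_cols = [c for c in sites.columns if c not in ("chrom", "pos", "bin")]
    merged = sites.merge(
        truth.loc[:, ["chrom", "pos", "genotype"]].rename(
            columns={"genotype": "truth_genotype"}
        ),
        on=["chrom", "pos"], how="left",
    )
    known = merged["truth_genotype"].notna()
    tallies = {g: 0 for g in GENOTYPE_STATES}
    for g, n in merged.loc[known, "truth_genotype"].value_counts().items():
        tallies[str(g)] = int(n)
    n_classified = sum(tallies.values())
    percentages = {
        g: round(100.0 * n / n_classified, 1) if n_classified else 0.0
        for g, n in tallies.items()
    }
    rep_gt = merged.loc[:, rep_cols].to_numpy(dtype=object)
    truth_gt = merged["truth_genotype"].to_numpy(dtype=object)
    missed = int(
        ((truth_gt == "het") & (rep_gt != "het").any(axis=1)).sum()
    )
    false_het = int(
        (np.isin(truth_gt, ["hom_ref", "hom_alt"]) & (rep_gt == "het").any(axis=1)).sum()
    )
    contributing = [b for b in BIN_LABELS if summary.discordant[b] > 0]
    denom = sum(summary.evaluated[b] for b in contributing)
    return DiscordanceClassification(
        tallies=tallies,
        unvalidated=int((~known).sum()),
        percentages=percentages,
        missed_het=missed,
        false_het=false_het,
        missed_het_rate=missed / denom if denom else 0.0,
        denominator=denom,
    )
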