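"""Synthetic pedigree exome-capture data with replicate structure.

Generates everything the analysis consumes, with the statistical structure
real replicate capture data shows at two scales:

* between-target heterogeneity — each target carries a log-normal capture
  efficiency shared by all its bases and by all libraries (a property of the
  probe, not of the library prep);
* within-replicate stochasticity — per-base depth is negative-binomially
  distributed around efficiency x replicate library scale, independently per
  replicate.

Truth genotypes follow Mendelian transmission through the pedigree except at
injected de novo sites (always on a double-hom_ref parental background, the
class a trio Mendelian test flags cleanly), and per-site allele counts are
binomial draws from the truth genotype with a Q20-like base-miscall rate.

Every draw is keyed by (seed, purpose, sample, replicate) so results are
fully deterministic and replicate streams are independent by construction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import DepthProfile, Pedigree, TargetRegions

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}
_BASES = np.array(list("ACGT"), dtype=object)


@dataclass
class SimulationParams:
    """All simulation knobs.

    Defaults emulate the study design the analysis is built for: a
    six-member three-generation family captured in triplicate, replicate
    mean target depths in the 48-86x range, heterogeneous per-target capture
    efficiency and overdispersed per-base depth.
    """

    seed: int = 0
    n_targets: int = 500
    target_length_mean: float = 200.0
    target_gap_mean: float = 150.0
    chrom: str = "chrS"
    #: sigma of the log-normal per-target capture efficiency (mean 1);
    #: 0 disables heterogeneity
    efficiency_sigma: float = 0.8
    #: fraction of targets whose probes essentially fail to capture
    #: (efficiency scaled by failed_target_efficiency)
    failed_target_fraction: float = 0.04
    failed_target_efficiency: float = 0.005
    #: replicate mean target depth drawn Uniform(low, high), in x units
    mean_depth_range: tuple[float, float] = (48.0, 86.0)
    #: negative-binomial size parameter k (variance = mu + mu^2/k);
    #: math.inf gives Poisson depth
    dispersion: float = 5.0
    #: expected heterozygous sites per kb in each founder
    het_density_per_kb: float = 0.8
    #: probability a sequenced base is miscalled
    base_error_rate: float = 0.01
    #: expected de novo mutations injected per trio child over the target space
    de_novo_per_child: float = 6.0
    min_call_depth: int = 10
    call_quality_threshold: float = 1.0
    #: fraction of targets labelled protein-coding (the exon subset)
    coding_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.target_length_mean <= 0 or self.target_gap_mean < 0:
            raise ValueError("target geometry must be positive")
        if self.efficiency_sigma < 0:
            raise ValueError("efficiency_sigma must be >= 0")
        lo, hi = self.mean_depth_range
        if lo < 0 or hi < lo:
            raise ValueError("mean_depth_range must satisfy 0 <= low <= high")
        if not self.dispersion > 0:
            raise ValueError("dispersion k must be > 0")
        if not 0 <= self.base_error_rate <= 1:
            raise ValueError("base_error_rate must be a probability")
        if self.het_density_per_kb < 0 or self.de_novo_per_child < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.coding_fraction <= 1:
            raise ValueError("coding_fraction must be in [0, 1]")
        if not 0 <= self.failed_target_fraction <= 1:
            raise ValueError("failed_target_fraction must be in [0, 1]")
        if self.failed_target_efficiency < 0:
            raise ValueError("failed_target_efficiency must be >= 0")


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Independent generator keyed by (seed, *key); stable across runs."""
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(words)


def default_pedigree() -> Pedigree:
    """Six individuals over three generations, as a replicate-WES family
    study would use: two founders, their child, a married-in founder, and
    two grandchildren."""
    return Pedigree(
        [
            ("GF01", None, None, 1),
            ("GM01", None, None, 2),
            ("MO01", "GF01", "GM01", 2),
            ("FA01", None, None, 1),
            ("CH01", "FA01", "MO01", 1),
            ("CH02", "FA01", "MO01", 2),
        ]
    )


def simulate_targets(params: SimulationParams) -> TargetRegions:
    """Non-overlapping exon-sized target intervals on one synthetic chromosome."""
    rng = _rng(params.seed, "targets")
    lengths = np.maximum(1, rng.poisson(params.target_length_mean, params.n_targets))
    gaps = rng.poisson(params.target_gap_mean, params.n_targets) + 1
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return TargetRegions(
        [(params.chrom, int(s), int(s + L)) for s, L in zip(starts, lengths)]
    )


def simulate_exons(targets: TargetRegions, params: SimulationParams) -> TargetRegions:
    """A deterministic subset of targets labelled protein-coding."""
    rng = _rng(params.seed, "exons")
    n = targets.n_intervals
    k = max(1, int(round(params.coding_fraction * n)))
    pick = np.sort(rng.choice(n, size=k, replace=False))
    ivs = targets.intervals
    return TargetRegions([ivs[i] for i in pick])


def target_efficiencies(targets: TargetRegions, params: SimulationParams) -> np.ndarray:
    """Per-target capture efficiency, length-weighted to mean 1.

    Keyed by seed only: the same targets get the same efficiencies in every
    replicate and individual, as for a shared capture kit.
    """
    if params.efficiency_sigma == 0 and params.failed_target_fraction == 0:
        return np.ones(targets.n_intervals)
    rng = _rng(params.seed, "efficiency")
    s = params.efficiency_sigma
    if s > 0:
        eff = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=targets.n_intervals)
    else:
        eff = np.ones(targets.n_intervals)
    if params.failed_target_fraction > 0:
        failed = rng.random(targets.n_intervals) < params.failed_target_fraction
        eff[failed] *= params.failed_target_efficiency
    eff /= np.average(eff, weights=targets.lengths)
    return eff


def replicate_mean_depth(
    params: SimulationParams, sample_id: str, replicate_id: str
) -> float:
    lo, hi = params.mean_depth_range
    if hi == lo:
        return float(lo)
    return float(_rng(params.seed, "scale", sample_id, replicate_id).uniform(lo, hi))


def simulate_replicate_depth(
    targets: TargetRegions,
    params: SimulationParams,
    sample_id: str,
    replicate_id: str,
    efficiency: np.ndarray | None = None,
    mean_depth: float | None = None,
) -> DepthProfile:
    """One library's per-base depth profile.

    Per-base mean = target efficiency x replicate mean depth; draws are
    negative binomial (Poisson when ``dispersion`` is infinite) and
    independent across replicates.
    """
    if efficiency is None:
        efficiency = target_efficiencies(targets, params)
    if mean_depth is None:
        mean_depth = replicate_mean_depth(params, sample_id, replicate_id)
    mu = np.repeat(efficiency, targets.lengths) * mean_depth
    rng = _rng(params.seed, "depth", sample_id, replicate_id)
    if math.isinf(params.dispersion):
        depth = rng.poisson(mu)
    else:
        k = params.dispersion
        depth = rng.negative_binomial(k, k / (k + mu))
    return DepthProfile(targets, depth, sample_id, replicate_id)


@dataclass
class TruthSet:
    """Ground-truth genotypes and injected de novo sites.

    ``genotypes`` holds alt-allele dosage (0/1/2) per variant site (rows,
    flat target coordinates) per individual (columns); ``dnm_sites`` maps
    each trio child to the flat positions of its injected de novo mutations.
    """

    targets: TargetRegions
    sites: np.ndarray                 # flat positions, sorted
    chroms: np.ndarray
    positions: np.ndarray             # 0-based genomic
    ref: np.ndarray
    alt: np.ndarray
    genotypes: pd.DataFrame           # index = flat site, columns = individuals
    dnm_sites: dict[str, np.ndarray]

    def genotype_tokens(self, sample_id: str) -> np.ndarray:
        tok = np.array(["hom_ref", "het", "hom_alt"], dtype=object)
        return tok[self.genotypes[sample_id].to_numpy()]

    def truth_table(self, sample_id: str) -> pd.DataFrame:
        """chrom/pos/genotype truth for one individual (all variant sites)."""
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "ref": self.ref,
                "alt": self.alt,
                "genotype": self.genotype_tokens(sample_id),
            }
        )


def simulate_pedigree_truth(
    targets: TargetRegions, pedigree: Pedigree, params: SimulationParams
) -> TruthSet:
    """Draw founder heterozygous sites, transmit through the pedigree, and
    inject de novo mutations on double-hom_ref backgrounds."""
    rng = _rng(params.seed, "truth")
    total = targets.total_bases
    founders = pedigree.founders()
    children = [t.child for t in pedigree.trios()]

    lam = params.het_density_per_kb * total / 1000.0
    founder_sites: dict[str, np.ndarray] = {}
    used: set[int] = set()
    for f in founders:
        n = min(rng.poisson(lam), total)
        sites = rng.choice(total, size=n, replace=False)
        founder_sites[f] = sites
        used.update(int(s) for s in sites)

    dnm_sites: dict[str, np.ndarray] = {}
    free = np.setdiff1d(np.arange(total), np.fromiter(used, dtype=np.int64))
    for c in children:
        n = min(rng.poisson(params.de_novo_per_child), free.size)
        pick = rng.choice(free.size, size=n, replace=False)
        dnm_sites[c] = np.sort(free[pick])
        free = np.delete(free, pick)

    all_sites = np.unique(
        np.concatenate(
            [s for s in founder_sites.values()]
            + [s for s in dnm_sites.values()]
            + [np.array([], dtype=np.int64)]
        )
    ).astype(np.int64)
    site_index = {int(s): i for i, s in enumerate(all_sites)}
    n_sites = all_sites.size

    ids = pedigree.topological_order()
    G = pd.DataFrame(
        np.zeros((n_sites, len(ids)), dtype=np.int8), index=all_sites, columns=ids
    )
    for f, sites in founder_sites.items():
        G.loc[np.sort(sites), f] = 1

    for iid in ids:
        ind = pedigree.individuals[iid]
        if ind.is_founder:
            continue
        if ind.father is None or ind.mother is None:
            raise ValueError(
                f"individual {iid!r} has exactly one known parent; the "
                "simulator requires both parents or neither"
            )
        gf = G[ind.father].to_numpy()
        gm = G[ind.mother].to_numpy()
        a = (gf == 2) | ((gf == 1) & (rng.random(n_sites) < 0.5))
        b = (gm == 2) | ((gm == 1) & (rng.random(n_sites) < 0.5))
        g = a.astype(np.int8) + b.astype(np.int8)
        for s in dnm_sites.get(iid, ()):
            g[site_index[int(s)]] = 1  # fresh site: both parents hom_ref
        G[iid] = g

    chroms, positions = targets.flat_to_genomic(all_sites)
    ref = _BASES[rng.integers(0, 4, size=n_sites)]
    alt = np.array([_ALT_OF[b] for b in ref], dtype=object)
    return TruthSet(
        targets=targets,
        sites=all_sites,
        chroms=chroms,
        positions=positions,
        ref=ref,
        alt=alt,
        genotypes=G,
        dnm_sites=dnm_sites,
    )


def simulate_allele_counts(
    truth: TruthSet,
    profile: DepthProfile,
    params: SimulationParams,
) -> pd.DataFrame:
    """Q20-filtered ref/alt base counts at every truth site for one library.

    Alt-allele probability is eps (hom_ref), 0.5 (het) or 1-eps (hom_alt)
    with eps the base miscall rate; counts are binomial in the library's
    depth at the site.
    """
    rng = _rng(params.seed, "counts", profile.sample_id, profile.replicate_id)
    depth = profile.depth[truth.sites]
    g = truth.genotypes[profile.sample_id].to_numpy()
    eps = params.base_error_rate
    p_alt = np.choose(g, [eps, 0.5, 1.0 - eps])
    alt = rng.binomial(depth, p_alt)
    return pd.DataFrame(
        {
            "chrom": truth.chroms,
            "pos": truth.positions,
            "ref": truth.ref,
            "alt": truth.alt,
            "sample": profile.sample_id,
            "replicate": profile.replicate_id,
            "ref_count": depth - alt,
            "alt_count": alt,
        }
    )


@dataclass
class SimulatedDataset:
    """One full synthetic study: targets, exon subset, pedigree, replicate
    depth profiles, truth genotypes and per-library allele counts."""

    params: SimulationParams
    targets: TargetRegions
    exons: TargetRegions
    pedigree: Pedigree
    replicate_ids: tuple[str, ...]
    profiles: dict[tuple[str, str], DepthProfile] = field(repr=False)
    truth: TruthSet = field(repr=False)
    counts: pd.DataFrame = field(repr=False)

    def replicate_profiles(self, sample_id: str) -> list[DepthProfile]:
        return [self.profiles[(sample_id, r)] for r in self.replicate_ids]

    def aggregate_profile(self, sample_id: str) -> DepthProfile:
        from .concordance import aggregate_profiles

        return aggregate_profiles(self.replicate_profiles(sample_id))

    def aggregate_counts(self) -> pd.DataFrame:
        """Allele counts summed over replicates, replicate id 'aggregate'."""
        agg = (
            self.counts.groupby(
                ["chrom", "pos", "ref", "alt", "sample"], as_index=False, sort=True
            )[["ref_count", "alt_count"]]
            .sum()
        )
        agg["replicate"] = "aggregate"
        return agg


def simulate_dataset(
    params: SimulationParams,
    pedigree: Pedigree | None = None,
    n_replicates: int = 3,
) -> SimulatedDataset:
    """Generate a complete synthetic replicate-capture study."""
    if pedigree is None:
        pedigree = default_pedigree()
    targets = simulate_targets(params)
    exons = simulate_exons(targets, params)
    eff = target_efficiencies(targets, params)
    replicate_ids = tuple(f"R{i + 1}" for i in range(n_replicates))
    profiles = {
        (iid, rid): simulate_replicate_depth(targets, params, iid, rid, efficiency=eff)
        for iid in pedigree.ids
        for rid in replicate_ids
    }
    truth = simulate_pedigree_truth(targets, pedigree, params)
    counts = pd.concat(
        [
            simulate_allele_counts(truth, profiles[(iid, rid)], params)
            for iid in pedigree.ids
            for rid in replicate_ids
        ],
        ignore_index=True,
    )
    return SimulatedDataset(
        params=params,
        targets=targets,
        exons=exons,
        pedigree=pedigree,
        replicate_ids=replicate_ids,
        profiles=profiles,
        truth=truth,
        counts=counts,
    )
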