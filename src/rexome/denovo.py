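"""Trio de novo mutation detection by Mendelian-inheritance violation.

A candidate de novo mutation (DNM) is a site where the child's genotype
cannot be formed by transmitting one allele from each parent, all three trio
members having confident (non-no_call) genotypes at or above a depth floor.
Biallelic autosomal sites only; genotypes are alt-allele dosages
{hom_ref: 0, het: 1, hom_alt: 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENOTYPE_STATES, NO_CALL, Pedigree, Trio

_GAMETES = {"hom_ref": (0,), "het": (0, 1), "hom_alt": (1,)}
_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2}


def enumerate_trios(pedigree: Pedigree) -> list[Trio]:
    """Every (child, father, mother) with both parents in the pedigree,
    in deterministic (sorted child id) order."""
    return pedigree.trios()


def mendelian_consistent(child: str, father: str, mother: str) -> bool:
    """True iff the child genotype can arise from one allele of each parent."""
    for g in (child, father, mother):
        if g not in GENOTYPE_STATES:
            raise ValueError(
                f"mendelian_consistent requires a confident genotype, got {g!r}"
            )
    possible = {a + b for a in _GAMETES[father] for b in _GAMETES[mother]}
    return _DOSAGE[child] in possible


#: consistency of every ordered (child, father, mother) triple, precomputed
_CONSISTENT = {
    (c, f, m): mendelian_consistent(c, f, m)
    for c in GENOTYPE_STATES
    for f in GENOTYPE_STATES
    for m in GENOTYPE_STATES
}


def detect_dnm(
    calls: pd.DataFrame,
    trio: Trio,
    min_depth: int = 10,
    replicate: str = "aggregate",
) -> pd.DataFrame:
    """Mendelian-violation sites for one trio in one replicate (or aggregate).

    *calls* is a genotype table covering the trio members for the requested
    ``replicate`` id.  A site is a DNM candidate iff all three members have
    depth >= *min_depth* and confident calls, and the genotype triple is
    Mendelian-inconsistent.  Returns columns chrom, pos, child, father,
    mother, child_gt, father_gt, mother_gt, min_depth_used.
    """
    sub = calls[calls["replicate"] == replicate]
    members = {"child": trio.child, "father": trio.father, "mother": trio.mother}
    for role, iid in members.items():
        if not (sub["sample"] == iid).any():
            raise ValueError(
                f"no genotype calls for trio {role} {iid!r} "
                f"in replicate {replicate!r}"
            )
    wide_gt = sub.pivot_table(
        index=["chrom", "pos"], columns="sample", values="genotype", aggfunc="first"
    )
    wide_dp = sub.pivot_table(
        index=["chrom", "pos"], columns="sample", values="depth", aggfunc="first"
    )
    cols = [trio.child, trio.father, trio.mother]
    gt = wide_gt.reindex(columns=cols).to_numpy(dtype=object)
    dp = wide_dp.reindex(columns=cols).to_numpy(dtype=float)
    ok = (
        ~pd.isna(gt).any(axis=1)
        & (gt != NO_CALL).all(axis=1)
        & (np.nan_to_num(dp, nan=-1.0) >= min_depth).all(axis=1)
    )
    violation = np.array(
        [ok_i and not _CONSISTENT[tuple(row)] for ok_i, row in zip(ok, gt)],
        dtype=bool,
    )
    idx = wide_gt.index[violation]
    out = pd.DataFrame(
        {
            "chrom": [c for c, _ in idx],
            "pos": [int(p) for _, p in idx],
            "child": trio.child,
            "father": trio.father,
            "mother": trio.mother,
            "child_gt": gt[violation, 0],
            "father_gt": gt[violation, 1],
            "mother_gt": gt[violation, 2],
            "min_depth_used": dp[violation].min(axis=1).astype(np.int64)
            if violation.any()
            else np.array([], dtype=np.int64),
        }
    )
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def dnm_concordance(
    replicate_calls: dict[str, pd.DataFrame], aggregate_calls: pd.DataFrame
) -> pd.DataFrame:
    """Per-site replicate support and aggregate status for DNM candidates.

    *replicate_calls* maps replicate id -> the :func:`detect_dnm` output for
    that replicate; *aggregate_calls* is the aggregate-mode output for the
    same trio and threshold.  Returns one row per candidate site with the
    number of supporting replicates (0-3), an ``in_aggregate`` flag, and a
    category: ``concordant`` (all replicates and aggregate),
    ``aggregate_only``, ``replicate_only``, or ``partial``.
    """
    rep_ids = sorted(replicate_calls)
    sites: dict[tuple, dict] = {}
    for rid in rep_ids:
        for _, row in replicate_calls[rid].iterrows():
            key = (row["chrom"], int(row["pos"]))
            sites.setdefault(key, {"support": 0, "in_aggregate": False})
            sites[key]["support"] += 1
    for _, row in aggregate_calls.iterrows():
        key = (row["chrom"], int(row["pos"]))
        sites.setdefault(key, {"support": 0, "in_aggregate": False})
        sites[key]["in_aggregate"] = True
    rows = []
    for (chrom, pos), info in sorted(sites.items()):
        if info["in_aggregate"] and info["support"] == len(rep_ids):
            cat = "concordant"
        elif info["in_aggregate"] and info["support"] == 0:
            cat = "aggregate_only"
        elif not info["in_aggregate"] and info["support"] > 0:
            cat = "replicate_only"
        else:
            cat = "partial"
        rows.append(
            {"chrom": chrom, "pos": pos, "support": info["support"],
             "in_aggregate": info["in_aggregate"], "category": cat}
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "support", "in_aggregate", "category"]
    )
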