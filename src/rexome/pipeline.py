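"""End-to-end orchestration: simulate -> coverage -> concordance ->
genotype -> de novo, returning one JSON-serialisable results bundle.

Used by the ``rexome all`` CLI subcommand and by the acceptance script; the
report renderer formats these results without recomputing anything.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from . import concordance as cc
from . import coverage as cov
from . import denovo as dn
from . import genotypes as gt
from .core import Pedigree
from .simulate import SimulatedDataset, SimulationParams, simulate_dataset

DEFAULT_THRESHOLDS = (1, 10, 20)


def _caller_eps(params: SimulationParams) -> float:
    # the caller's error model needs eps in (0, 0.5); keep a Q40 floor so a
    # zero-error simulation is still callable
    return max(params.base_error_rate, 1e-4)


def coverage_results(ds: SimulatedDataset, thresholds=DEFAULT_THRESHOLDS) -> dict:
    out: dict[str, Any] = {"thresholds": list(thresholds), "samples": {}}
    for iid in ds.pedigree.ids:
        reps = ds.replicate_profiles(iid)
        agg = ds.aggregate_profile(iid)
        summ = cov.replicate_summary(reps, thresholds)
        out["samples"][iid] = {
            "replicate_ids": summ.replicate_ids,
            "replicate_mean_depth": summ.mean_depths,
            "replicate_pct": {str(t): v for t, v in summ.replicate_pct.items()},
            "mean_sd": {str(t): list(v) for t, v in summ.mean_sd.items()},
            "aggregate_mean_depth": round(cov.mean_target_depth(agg), 1),
            "aggregate_pct": {
                str(t): round(v, 1)
                for t, v in cov.percent_target_at(agg, thresholds).items()
            },
        }
    return out


def concordance_results(
    ds: SimulatedDataset, thresholds=(20, 1), min_seg_len: int = 50
) -> dict:
    out: dict[str, Any] = {"samples": {}}
    for iid in ds.pedigree.ids:
        reps = ds.replicate_profiles(iid)
        agg = ds.aggregate_profile(iid)
        sample: dict[str, Any] = {}
        for t in thresholds:
            masks = [cov.coverage_mask(p, t) for p in reps]
            res = cc.iut(masks)
            agg_mask = cov.coverage_mask(agg, t)
            rec = cc.recovered_mask(agg_mask, masks)
            entry: dict[str, Any] = {
                "venn": res.venn,
                "n_total": res.n_total,
                "intersection_count": res.intersection_count,
                "union_count": res.union_count,
                "variable_count": res.variable_count,
                "intersection_pct": round(res.intersection_pct, 1),
                "variable_pct": round(res.variable_pct, 1),
                "uncovered_pct": round(res.uncovered_pct, 1),
                "aggregate_covered_count": agg_mask.covered_count,
                "recovered_count": rec.covered_count,
            }
            if t == 20:
                segs = cc.segments_from_mask(rec)
                freq, power, mean_len = cc.segment_length_distribution(segs)
                n_long = int((segs.lengths > min_seg_len).sum())
                n_ov, ov_bases = cc.intersect_segments_exons(
                    segs, ds.exons, min_len=min_seg_len
                )
                entry.update(
                    {
                        "n_segments": segs.n_segments,
                        "n_singletons": freq.get(1, 0),
                        "mean_segment_length": round(mean_len, 1)
                        if segs.n_segments
                        else None,
                        "powerlaw_slope": round(power.slope, 3) if power else None,
                        "powerlaw_r2": round(power.r_squared, 3) if power else None,
                        "n_segments_gt_min_len": n_long,
                        "n_segments_overlapping_exons": n_ov,
                        "overlapped_coding_bases": ov_bases,
                    }
                )
            sample[f"ge{t}x"] = entry
        out["samples"][iid] = sample
    return out


def genotype_results(ds: SimulatedDataset) -> dict:
    params = ds.params
    calls = gt.call_table(
        ds.counts,
        base_error_rate=_caller_eps(params),
        min_call_depth=params.min_call_depth,
        quality_threshold=params.call_quality_threshold,
    )
    out: dict[str, Any] = {"samples": {}, "totals": {}}
    tot_eval = {b: 0 for b in gt.BIN_LABELS}
    tot_disc = {b: 0 for b in gt.BIN_LABELS}
    tot_class = {g: 0 for g in ("het", "hom_ref", "hom_alt")}
    tot_missed = 0
    tot_denom = 0
    for iid in ds.pedigree.ids:
        bins = gt.bin_positions(ds.replicate_profiles(iid))
        summ = gt.discordance(calls[calls["sample"] == iid], bins, ds.targets)
        clas = gt.classify_discordances(summ, ds.truth.truth_table(iid))
        out["samples"][iid] = {
            "evaluated": summ.evaluated,
            "discordant": summ.discordant,
            "rate_per_1e6": summ.rates_per_million(),
            "truth_tallies": clas.tallies,
            "missed_het": clas.missed_het,
            "false_het": clas.false_het,
        }
        for b in gt.BIN_LABELS:
            tot_eval[b] += summ.evaluated[b]
            tot_disc[b] += summ.discordant[b]
        for g in tot_class:
            tot_class[g] += clas.tallies[g]
        tot_missed += clas.missed_het
        tot_denom += clas.denominator
    out["totals"] = {
        "evaluated": tot_eval,
        "discordant": tot_disc,
        "rate_per_1e6": {
            b: round(1e6 * tot_disc[b] / tot_eval[b], 1) if tot_eval[b] else 0.0
            for b in gt.BIN_LABELS
        },
        "truth_tallies": tot_class,
        "missed_het": tot_missed,
        "missed_het_denominator": tot_denom,
    }
    out["_calls"] = calls  # stripped before JSON serialisation
    return out


def denovo_results(ds: SimulatedDataset, calls=None) -> dict:
    params = ds.params
    if calls is None:
        calls = gt.call_table(
            ds.counts,
            base_error_rate=_caller_eps(params),
            min_call_depth=params.min_call_depth,
            quality_threshold=params.call_quality_threshold,
        )
    agg_calls = gt.call_table(
        ds.aggregate_counts(),
        base_error_rate=_caller_eps(params),
        min_call_depth=params.min_call_depth,
        quality_threshold=params.call_quality_threshold,
    )
    trios = dn.enumerate_trios(ds.pedigree)
    out: dict[str, Any] = {"trios": {}}
    for trio in trios:
        trio_out: dict[str, Any] = {
            "father": trio.father,
            "mother": trio.mother,
            "injected": int(ds.truth.dnm_sites.get(trio.child, np.array([])).size),
        }
        for t in (10, 20):
            per_rep = {
                rid: dn.detect_dnm(calls, trio, min_depth=t, replicate=rid)
                for rid in ds.replicate_ids
            }
            agg = dn.detect_dnm(agg_calls, trio, min_depth=t, replicate="aggregate")
            conc = dn.dnm_concordance(per_rep, agg)
            injected = set(int(s) for s in ds.truth.dnm_sites.get(trio.child, ()))
            found_agg = set(
                int(f)
                for f in ds.targets.locate_table(
                    agg["chrom"].to_numpy(), agg["pos"].to_numpy()
                )
            ) if len(agg) else set()
            trio_out[f"min_depth_{t}"] = {
                "replicate_counts": {rid: len(df) for rid, df in per_rep.items()},
                "aggregate_count": len(agg),
                "aggregate_true_positives": len(found_agg & injected),
                "aggregate_only": int((conc["category"] == "aggregate_only").sum()),
                "replicate_only": int((conc["category"] == "replicate_only").sum()),
                "concordant": int((conc["category"] == "concordant").sum()),
            }
        out["trios"][trio.child] = trio_out
    return out


def run_full_analysis(
    params: SimulationParams,
    pedigree: Pedigree | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    min_seg_len: int = 50,
) -> dict:
    """Simulate a dataset and run every analysis stage on it."""
    ds = simulate_dataset(params, pedigree=pedigree)
    genotype = genotype_results(ds)
    calls = genotype.pop("_calls")
    return {
        "seed": params.seed,
        "n_target_bases": ds.targets.total_bases,
        "coverage": coverage_results(ds, thresholds),
        "concordance": concordance_results(ds, min_seg_len=min_seg_len),
        "genotype": genotype,
        "denovo": denovo_results(ds, calls=calls),
    }
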