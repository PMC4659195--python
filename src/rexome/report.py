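"""Purely presentational report rendering.

Every number printed here comes from a results dictionary produced by
:mod:`rexome.pipeline` (or reloaded from its JSON serialisation); the
renderer only formats, it never computes.
"""

from __future__ import annotations


def pct(x: int, n: int) -> float:
    """A count as an unrounded percentage of a denominator."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * x / n


def rate_per_million(x: int, n: int) -> float:
    """A count as a rate in units of 1e-6 (the discordance convention)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 1e6 * x / n


def _fmt_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.1f} ± {sd:.1f}"


def render_report(results: dict) -> str:
    """Render the full pipeline results as a markdown report."""
    lines: list[str] = []
    lines.append("# Replicate exome analysis report")
    lines.append("")
    lines.append(f"Seed: {results['seed']}; target bases: {results['n_target_bases']}")
    lines.append("")

    covr = results["coverage"]
    thresholds = covr["thresholds"]
    lines.append("## Coverage summary (per individual)")
    lines.append("")
    header = "| Sample | Mean target depth | " + " | ".join(
        f"% ≥{t}x" for t in thresholds
    ) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (2 + len(thresholds)))
    for iid, s in covr["samples"].items():
        for i, rid in enumerate(s["replicate_ids"]):
            cells = [f"{s['replicate_pct'][str(t)][i]:.1f}" for t in thresholds]
            lines.append(
                f"| {iid} {rid} | {s['replicate_mean_depth'][i]:.1f}x | "
                + " | ".join(cells) + " |"
            )
        cells = [_fmt_mean_sd(*s["mean_sd"][str(t)]) for t in thresholds]
        lines.append(f"| {iid} mean ± SD | | " + " | ".join(cells) + " |")
        cells = [f"{s['aggregate_pct'][str(t)]:.1f}" for t in thresholds]
        lines.append(
            f"| {iid} aggregate | {s['aggregate_mean_depth']:.1f}x | "
            + " | ".join(cells) + " |"
        )
    lines.append("")

    lines.append("## Replicate intersection–union analysis")
    lines.append("")
    for iid, s in results["concordance"]["samples"].items():
        for key, e in s.items():
            t = key[2:-1]
            lines.append(
                f"- {iid} ≥{t}x: intersection {e['intersection_count']} "
                f"({e['intersection_pct']:.1f}%), variable {e['variable_count']} "
                f"({e['variable_pct']:.1f}%), uncovered {e['uncovered_pct']:.1f}%, "
                f"recovered by aggregate {e['recovered_count']}"
            )
            if "n_segments" in e and e["n_segments"]:
                lines.append(
                    f"  - recovered segments: {e['n_segments']} "
                    f"(singletons {e['n_singletons']}, mean length "
                    f"{e['mean_segment_length']} bp, power-law slope "
                    f"{e['powerlaw_slope']}); "
                    f">{50} bp overlapping exons: "
                    f"{e['n_segments_overlapping_exons']} segments, "
                    f"{e['overlapped_coding_bases']} coding bases"
                )
    lines.append("")

    g = results["genotype"]["totals"]
    lines.append("## Replicate genotype discordance (all individuals)")
    lines.append("")
    lines.append("| Bin | Evaluated | Discordant | Rate (x10^-6) |")
    lines.append("|---|---|---|---|")
    for b in g["evaluated"]:
        lines.append(
            f"| {b} | {g['evaluated'][b]} | {g['discordant'][b]} | "
            f"{g['rate_per_1e6'][b]:.1f} |"
        )
    tal = g["truth_tallies"]
    lines.append("")
    lines.append(
        f"Truth classification of discordant sites: het {tal['het']}, "
        f"hom_ref {tal['hom_ref']}, hom_alt {tal['hom_alt']}; "
        f"missed hets {g['missed_het']} of {g['missed_het_denominator']} "
        "evaluated positions in contributing bins"
    )
    lines.append("")

    lines.append("## De novo mutations (per trio)")
    lines.append("")
    trios = results["denovo"]["trios"]
    if not trios:
        lines.append("No trios in pedigree: 0 de novo candidates.")
    for child, tr in trios.items():
        lines.append(f"- Trio child {child} (injected {tr['injected']}):")
        for t in (10, 20):
            e = tr[f"min_depth_{t}"]
            reps = ", ".join(f"{r}={n}" for r, n in e["replicate_counts"].items())
            lines.append(
                f"  - ≥{t}x: replicates {reps}; aggregate "
                f"{e['aggregate_count']} ({e['aggregate_true_positives']} true); "
                f"aggregate-only {e['aggregate_only']}, "
                f"replicate-only {e['replicate_only']}, "
                f"concordant {e['concordant']}"
            )
    lines.append("")
    return "\n".join(lines)
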