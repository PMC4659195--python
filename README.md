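# rexome

Replicate-aware whole-exome sequencing (WES) analysis: how much of a capture
target does a single library *reliably* cover, how much is stochastic, and
what does merging technical replicates buy you for genotyping and trio
de novo detection?

When the same DNA sample is captured and sequenced several times, the set of
target bases reaching a usable depth (conventionally ≥20x) differs between
libraries even at equal input. `rexome` quantifies this with a per-base
**intersection–union analysis** over *k* = 3 replicate coverage masks
`M_r(t) = {i : depth_r(i) ≥ t}`:

- intersection `I = |M₁ ∩ M₂ ∩ M₃|` — bases usable in every library,
- union `U = |M₁ ∪ M₂ ∪ M₃|` — bases usable in at least one,
- variable fraction `V/N = (U − I)/N` — the stochastically covered share of
  the `N` targeted bases.

Around this core it provides: Table-style coverage summaries (mean target
depth, % target ≥1x/≥10x/≥20x, replicate mean ± SD), loess (span 0.75)
coverage-saturation trends with 95% bands, per-base **aggregation** of
replicates (the depth-space equivalent of a BAM merge) and extraction of the
*recovered* segments (aggregate-covered bases outside the replicate
intersection) with power-law length characterisation and coding-exon
intersection, a three-genotype binomial Bayes caller with depth-binned
(10-19x / 20-29x / ≥30x) **replicate genotype discordance**, and trio
**de novo mutation (DNM)** detection by Mendelian-inheritance violation with
replicate/aggregate concordance.

Everything runs on plain-text inputs (BED targets, samtools-depth-style
TSVs, PED pedigrees, a VCF-lite genotype/allele-count TSV), and a built-in
simulator generates complete synthetic pedigree-capture studies — 6
individuals over three generations, 3 technical replicates each, replicate
mean depths in the 48–86x range, log-normal per-target capture efficiency,
negative-binomial per-base depth, Mendelian truth genotypes with injected
DNMs — so every stage is testable without sequencing data.

## Worked example

```python
from rexome import (SimulationParams, simulate_dataset, coverage_mask,
                    iut, replicate_summary, percent_target_at)

ds = simulate_dataset(SimulationParams(seed=1))       # 6 individuals x 3 replicates
reps = ds.replicate_profiles("GF01")
agg = ds.aggregate_profile("GF01")

summ = replicate_summary(reps)
print("replicate %>=20x:", summ.replicate_pct[20], "mean±SD:", summ.mean_sd[20])
print("aggregate %>=20x:", round(percent_target_at(agg)[20], 1))

res = iut([coverage_mask(p, 20) for p in reps])
print(f"IUT >=20x: intersection {res.intersection_count} "
      f"({res.intersection_pct:.1f}%), variable {res.variable_count} "
      f"({res.variable_pct:.1f}%) of {res.n_total}")
```

prints

```
replicate %>=20x: [81.1, 79.6, 82.0] mean±SD: (80.9, 1.2)
aggregate %>=20x: 94.6
IUT >=20x: intersection 69786 (69.6%), variable 20634 (20.6%) of 100223
```

Each replicate of this simulated individual covers ~80% of the 100,223
targeted bases at ≥20x, but only 69.6% is covered in *all three* libraries:
20.6% of the target is stochastically usable, and merging the replicates
lifts usable coverage to 94.6%. At ≥1x the variable fraction collapses to
~3% — variability concentrates at the genotypeability threshold, not at
bare sequencability.

The same analyses are available from the shell:

```bash
rexome simulate --seed 1 --out-dir sim/
rexome concordance --depth sim/depth_GF01_R1.tsv --depth sim/depth_GF01_R2.tsv \
    --depth sim/depth_GF01_R3.tsv --targets sim/targets.bed \
    --exons sim/exons.bed --out-json iut.json --out-segments segments.bed
rexome all --seed 1 --out-dir run/     # full pipeline + report.md + manifest
```

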