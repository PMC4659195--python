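# Methods

## The analysis

`rexome` treats a whole-exome experiment as a dense per-base depth vector
over a merged, sorted target interval set (0-based half-open everywhere
internally; samtools-style 1-based coordinates are converted at the file
boundary). All set operations — threshold masks, Venn membership,
aggregation, segment extraction — are exact vectorised operations on that
flat index, so the conservation identities of the intersection–union
analysis (Σ of the 7 Venn regions = union; intersection + variable = union;
union + uncovered = N) hold by construction and are asserted on every run.

**Coverage masks and the intersection–union analysis.** A base is covered
at threshold *t* iff its Q20-filtered depth is ≥ *t* (inclusive). For three
replicate masks the per-base membership triple is classified in one pass
into the 7 non-empty Venn regions. The variable count V = U − I measures
stochastic capture: bases usable in at least one but not all libraries.

**Two-proportion test.** Equality of two binomial proportions is tested
with the 2×2 chi-square, optionally with the clipped Yates continuity
correction, matching R's two-group `prop.test` (implemented via
`scipy.stats.chi2_contingency`; the unit tests verify it against the
hand-written contingency-table formula to 1e-10). A zero column margin
means identical proportions and returns χ² = 0, p = 1. p-values are kept
unrounded; formatting happens only in the report layer.

**Aggregation and recovered segments.** The aggregate profile is the
per-base sum of an individual's replicate depths (the depth-space
equivalent of merging BAMs). A base is *recovered* iff the aggregate
reaches the threshold and the replicate **intersection** does not; the CLI
also exposes a union baseline. Recovered bases are reduced to maximal runs
that never span the gap between target intervals; the run-length frequency
spectrum is summarised by an ordinary least-squares slope on
(log₁₀ length, log₁₀ frequency) — a descriptive power-law fit, not a
maximum-likelihood exponent estimate. Segments strictly longer than 50 bp
are intersected with coding exons (a segment counts once if it overlaps at
least one exon base; overlap bases are summed per segment).

**Genotype caller.** A stand-in for a most-probable-genotype Bayesian
caller: at a biallelic site with ref/alt Q20 base counts, the alt count is
binomial with alt probability ε (hom_ref), 0.5 (het) or 1 − ε (hom_alt),
where ε is the per-base miscall rate (default 0.01, i.e. Q20). With a prior
(flat by default) the call is the posterior argmax and its quality is the
log₁₀ posterior ratio best:second. Calls with depth < 10 or quality below
the threshold (default 1.0, i.e. 10:1 posterior odds — chosen so that
clean sites at the 10x floor, whose hom-ref quality is ≈ 3, remain
callable) are `no_call`.

**Discordance.** Every target position of an individual is binned by the
*minimum* depth across its replicates (10-19x, 20-29x, ≥30x; minimum is
the conservative choice guaranteeing every replicate meets the bin floor;
a mean rule is available via `--bin-stat`). A site is discordant iff the
replicate genotypes are not all identical; sites with any `no_call` are
excluded from numerator and denominator (an absent call cannot disagree).
Positions absent from the candidate-site table are implicitly concordant
reference calls. Rates are reported in units of 10⁻⁶. Discordant sites are
classified against truth genotypes (the role Sanger re-sequencing plays
for real data): missed-het = truth het with ≥1 non-het replicate call;
false-het = truth hom with ≥1 het replicate call; the missed-het rate's
denominator is the positions evaluated in the bins that contributed
discordant sites.

**De novo detection.** Genotypes are alt-allele dosages {0, 1, 2}; a trio
site violates Mendelian inheritance iff the child dosage cannot be written
as one gamete from each parent (exactly 12 of the 27 ordered triples).
A DNM candidate requires confident calls and depth ≥ the threshold (10 or
20) in all three members; sites failing that in any member are unevaluable
rather than negative. Replicate/aggregate concordance labels each candidate
site by its replicate support (0–3) and aggregate status. X/Y inheritance,
multi-allelic sites and indels are out of scope; no mutation-rate prior or
population-frequency filter is applied.

**Loess saturation trend.** Coverage versus input is smoothed with
locally weighted linear regression (statsmodels `lowess`, span 0.75). The
pointwise 95% band is `fit ± 1.96·SE` with SE from a residual bootstrap
(200 refits), so the band always contains the fitted line. The smoother's
contract is behavioural — it reproduces straight lines exactly and larger
spans give smoother curves — rather than coefficient-level, since no
reference coefficients exist for this analysis.

## The simulator

The generator emulates the study design the analysis is built for: a
six-member three-generation family (two founders, their child, a
married-in founder, two grandchildren → three trios), three technical
replicates per individual.

Capture depth has two variance scales:

- **between targets** — each target carries a log-normal efficiency
  (σ = 0.8, mean 1, length-weighted), shared by all libraries, as a
  property of the probe; additionally 4% of targets are capture failures
  (efficiency ×0.005), giving the few percent of target bases that real
  kits never sequence at any input;
- **within a library** — per-base depth is negative binomial with mean
  efficiency × replicate mean depth and dispersion k = 5; replicate mean
  depths are drawn Uniform(48, 86)x, the range reported for real
  triplicate capture libraries, so the per-individual aggregate lands near
  3× that (≈ 180-200x).

This calibration reproduces the observed real-data magnitudes — replicate
coverage ≈ 96% at ≥1x and ≈ 80% at ≥20x, aggregate ≈ 94% at ≥20x, and a
variable fraction much larger at ≥20x than at ≥1x. Founders get
heterozygous sites at 0.8/kb (exome-like density); children inherit one
uniformly chosen allele per parent; ~6 DNMs per trio child (matching
reported per-trio candidate counts) are injected at fresh sites whose
parents are hom_ref, so every injected site is a guaranteed Mendelian
violation and truth-versus-called recall is well defined. Allele counts
are binomial in the library's depth at the site with alt probability
ε / 0.5 / 1 − ε.

Determinism: every draw comes from a generator keyed by
(seed, purpose, sample, replicate) via CRC-32 of the key words, so any
artefact can be regenerated independently and replicate streams are
independent by construction.

**What the simulator does not model**, and hence what passing tests do not
show about real data: per-base depths within a target are conditionally
independent given the target's efficiency — there is no probe-tiling
spatial autocorrelation, so recovered segments are much shorter (mean
~2 bp) than the ~50 bp seen in real aggregate data; no GC or mappability
structure, so the mis-mapping-driven false-het class that dominates real
discordance validation is absent and synthetic discordance is rarer and
mostly missed hets; no read-level effects (duplicates, strand bias,
indels). Synthetic discordance counts are therefore far below the tens
observed across ~10⁸ real binned positions; the monotone decline of the
rate across depth bins is still asserted, but often as 0 ≥ 0 ≥ 0 at the
default study size.

## Problem sizes and numerical choices

Default synthetic studies use 500 targets of mean length 200 bp
(~10⁵ target bases), which the test suite and the acceptance script run
end-to-end in seconds; these sizes give Monte-Carlo errors comfortably
inside the 3-SE assertions used throughout. Percentages are reported to
one decimal; replicate dispersion is the sample SD (n − 1); rates use
units of 10⁻⁶. Closed-form checks (Poisson survival function for
percent-covered; binomial posteriors via scipy's pmf) act as independent
oracles for the simulation and the caller. Degenerate inputs are defined,
not accidental: empty masks yield empty segment sets; fewer than two
distinct segment lengths yield a histogram but no slope; duplicate x
values are legal in the loess fit; a zero column margin in the proportion
test returns p = 1.

## Known limitations

- The recovered-segment length spectrum is realistic in family (power-law
  like) but not in scale (see above).
- The genotype caller is a contract-level stand-in for the Bayesian
  callers used on real pileups; it ignores mapping quality, strand and
  base-quality heterogeneity beyond a single ε.
- The discordance denominator counts candidate-free positions as
  concordant reference calls, which matches how real all-position
  evaluations are tallied but means the numerator comes entirely from the
  candidate-site table.
- Trio detection operates on genotypes only; it does not require the
  child's variant allele to be absent from parental *reads*, so real-data
  use would need a downstream read-level filter.
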