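# Methods

## The experiment being modeled

A double-stranded ancient-DNA library is a finite pool of distinct template
molecules. Three classes matter for Y-chromosome work: endogenous chrY
templates, endogenous non-Y templates, and exogenous (environmental)
templates, which dominate poorly preserved material. Sequencing samples
templates with replacement (amplification plus cluster generation), so reads
sharing a template are PCR duplicates; hybridization capture thins the pool
before sequencing, preferentially retaining templates that overlap the probe
design. The analyses evaluate four conditions per sample: no enrichment
(pre-capture), Y-chromosome capture (YCC), whole-genome capture (WGC), and
WGC followed by YCC, the last expressed literally as two consecutive capture
rounds so the attendant complexity loss is mechanistic, not assumed.

## Simulator

**Pool.** `pool_size` templates; origin drawn per template from
(endogenous_fraction × y_fraction_of_endogenous,
endogenous_fraction × (1 − y_fraction_of_endogenous),
1 − endogenous_fraction). Exogenous templates live on a dedicated
pseudo-reference ten times the endogenous genome length, so they are
"sequenced but unmapped" downstream while still supporting coordinate
deduplication of the truth labels. Fragment lengths are truncated normal
above `min_length`; coordinates are uniform per reference; everything is
0-based half-open, BED dialect on disk.

**Capture.** Each template is retained independently with probability
(class probability) × (length multiplier). Class probabilities are
`p_on_target` (≥1-bp overlap with a target interval), `p_off_target_y`
(same reference, no overlap), `p_background` (everything else), constrained
`p_background ≤ p_off_target_y ≤ p_on_target`. The length multiplier is a
logistic `1 / (1 + exp(−(len − midpoint)/scale))`, midpoint defaulting to the
105-bp probe length: hybridization favours fragments comparable to or longer
than the probe, which reproduces the observed post-capture fragment-length
shift. `length_bias_scale = 0` disables the bias; the default demo scale of
40 bp retains a usable share of 60–70-bp fragments, matching the observation
that capture shifts but does not truncate aDNA length distributions.
A whole-genome pseudo-target (reference `*`, matching every mapped
reference) expresses WGC through the same operation.

**Sequencing.** `n_reads` draws with replacement, uniform template weights —
no amplification efficiency or GC bias. Consequently the expected number of
distinct templates after n reads from a pool of size P is the occupancy
formula `P (1 − (1 − 1/P)^n)`, which serves as the independent oracle for
both the simulator and the complexity extrapolator. Base sequences, sequencing
error within reads, adapters, alignment, and C→T deamination damage are
deliberately not simulated; reads inherit template coordinates exactly.

**Genotypes.** For a chosen true haplogroup, SNP sites on its root path carry
the derived allele, all others the ancestral; per-site depth is
Poisson(`mean_depth`), matching the 0.04–0.28× regime of real captured
libraries when set low; errors flip a base to a uniformly random other base;
base qualities straddle the calling floor (15% in 2–12, 85% in 20–40) so the
quality filter is always exercised.

## Accounting

Reads are duplicates iff they share (reference, start, end, strand) — both
ends plus strand rather than 5′ start only, which on truth-labeled synthetic
reads can never merge distinct templates. The representative is the
lexicographically smallest read id (deterministic). A read is on-target iff
it overlaps any target interval by ≥ 1 bp (half-open, via an interval tree;
tests cross-check a quadratic scan). Conditions are compared at matched
effort by down-sampling every condition to the per-individual minimum
retained read count, 10 replicates by default, replicate r seeded
`base_seed + r`; raw reads are down-sampled first and deduplicated after,
matching the order of the processing pipeline the metrics mirror.

Percentage conventions: "% of sequenced on-target" = unique on-target /
total down-sampled reads; "% of chrY on-target" = unique on-target / unique
chrY; clonality = duplicate fraction of mapped reads. Zero-denominator ratios
are reported as missing (`None`, printed `-`), never as 0. Display rounding
is decimal half-up — two decimals for % of sequenced, whole percent for % of
chrY, one decimal for fold-enrichment — applied only at the formatting layer;
all stored values are full precision. Fold-enrichment display values are
computed in `decimal` arithmetic because binary-float division of printed
means can land a hair under a `.x5` boundary (16191 / 16.8 is exactly 963.75
only in decimal).

Binomial proportion intervals are Wilson score intervals
(`statsmodels.stats.proportion.proportion_confint`), clamped so 0 successes
gives a lower bound of exactly 0. Across down-sampling replicates, proportion
means are pooled (summed numerators over summed denominators), which equals
the simple replicate mean whenever denominators are equal — guaranteed for
total-read denominators by construction — and guarantees every Wilson CI
brackets its mean. The fragment-length comparison is a standard two-sided
paired t-test on per-library mean lengths, with zero-variance differences
flagged degenerate instead of propagating NaN.

## Fold-enrichment

`fold(c1, c2) = mean unique on-target(c1) / mean unique on-target(c2)` at
matched down-sampled effort; when the baseline mean is 0 (or missing — a
library whose replicates never yielded an on-target read), the numerator mean
itself is reported. This zero-substitution convention reproduces every cell
of the published benchmark grid, including the low-endogenous columns; an
alternative "maximum across replicates as baseline" convention exists in the
literature but is not implemented because no benchmark cell exercises it.
The standard grid has six ordered pairs: YCC/pre, YCC/WGC, YCC/WGC+YCC,
WGC/pre, WGC+YCC/pre, WGC+YCC/WGC.

## Complexity extrapolation

The duplicate-count histogram n_j (distinct templates seen exactly j times)
is the sufficient statistic. Per-template read counts are modeled negative
binomial — a Gamma mixture of Poissons capturing unequal template
"sequenceability" — and the unseen zero class is recovered by EM on the
zero-truncated likelihood:

- E-step: `n0 = D · p0 / (1 − p0)`, `p0 = (1 + μ/r)^(−r)`;
- M-step: `μ = N / (D + n0)` in closed form; `r` by bounded 1-d profile
  likelihood over `log10 r ∈ [−4, 8]` (the upper bound covers the Poisson
  limit without overflow; `p0` is evaluated via `exp(−r·log1p(μ/r))`).

Library size is `L = D / (1 − p0)` and expected yield at effort multiplier t
is `L (1 − (1 + tμ/r)^(−r))` — increasing, concave, interpolating the
observed distinct count at t = 1 by construction. Convergence tolerance is
1e-6 relative on (μ, r, n0), at most 100 iterations; tightening to 1e-8
changes estimates only in the 6th digit. A histogram with only singletons
carries no curvature information and raises a no-duplicates signal; callers
fall back to the linear model `yield(n) = n · unique/total`, the behaviour
used for duplicate-free shotgun libraries.

Effort grids are expressed in total sequenced reads (default 50 log-spaced
points over 1e2–1e7) and converted to on-target effort through the library's
on-target read fraction before model evaluation, so curves answer "how many
unique on-target reads after n total reads".

**Bootstrap.** Uncertainty comes from resampling the histogram: each of
`n_boot` (default 100) replicates draws D template classes with replacement
from the observed classes, refits (or falls back), and re-extrapolates
normalized to its own resampled read total; per-grid-point medians and
variances are reported. Classes — not individual reads — are resampled: a
read-level multinomial bootstrap sheds ~E[e^−j] of singleton classes per
replicate, so every refit interpolates a distinct count systematically below
the observed one (about 10% low at mean multiplicity 3), biasing the whole
median curve; the class bootstrap keeps each replicate anchored to its own
observed distinct count, which is the behaviour the standard complexity
software exhibits. Enrichment curves are pointwise ratios of two bootstrap
median curves on a shared grid; zero-denominator points are missing (NaN) —
the zero-substitution rule applies only to the table point estimates, not to
curves. When both libraries are in their linear regimes the curve is flat;
once the captured library saturates over a still-linear baseline the ratio
decays, which is why projected enrichment "decelerates" for low-complexity
libraries.

## Sex and haplogroup inference

`Ry = n_Y / (n_X + n_Y)` over unique mapped sex-chromosome reads, with a 95%
normal-approximation CI (`±1.96·√(Ry(1−Ry)/n)`, clipped to [0, 1]) — the
normal interval, not Wilson, to stay faithful to the procedure this statistic
is cited from. The call is consistent-with-XY only when the entire CI exceeds
the threshold (default 0.075, configurable), not-consistent only when the CI
lies entirely below, indeterminate otherwise.

Haploid genotypes: per site, bases under the quality floor (default Phred 13,
inclusive) are discarded and one survivor is sampled uniformly; all bases
observed at a site are pooled before sampling. Assignment scores each call
against the tree's SNPs and returns the deepest node whose own branch carries
≥ 1 derived call. Tie-break among equally deep candidates (possible only
across siblings, via conflicting data): more derived calls along the root
path wins; a residual tie is reported unresolved with both candidates listed.
Derived calls off the chosen path are returned as conflicts, never silently
resolved, and a node whose own branch lacks a derived call is never named.
No derived call anywhere yields the unresolved marker, mirroring dash rows in
real result tables. SNP alleles are taken reference-forward; no strand
flipping. Trees load from a 6-column TSV (haplogroup, parent, snp_id,
position, ancestral, derived) validated for a single root, acyclicity, and
globally unique positions.

## Pipeline defaults and problem sizes

The built-in demo configuration runs two samples against a 100-region,
400-kb target design on a 1-Mb miniature chrY: a well-preserved library
(1.54% endogenous, 92 ± 15 bp fragments) and a poorly preserved one (0.03%,
66 ± 12 bp), pools of 5×10^5 templates sequenced at 2–2.5×10^4 reads per
condition, YCC retention (0.9 / 0.05 / 1e-4), WGC retention (0.6 endogenous,
0.3 background — whole-genome capture enriches host molecules but its output
remains dominated by environmental ones), 20 bootstrap replicates and a
30-point effort grid. At this scale the full run takes ~20 s; the chrY share
of endogenous templates (0.2) is over-represented relative to a real genome
so that on-target counts remain informative at five-thousandth the real pool
size, and fold-enrichment magnitudes compress accordingly — direction and
ordering of effects, not their absolute size, are the reproducible content.
Test suites use further-scaled pools (1e2–1e4) chosen so every stochastic
check retains its stated statistical power.

All stage seeds derive from one run seed via CRC32 of labeled strings
(stable, < 2^31), recorded in the manifest; identical configs reproduce
byte-identical artifacts.

## What passing tests do and do not show

The simulator realizes exactly the assumptions the estimators make (uniform
amplification, independent capture, coordinate-faithful reads). Passing
recovery tests therefore validates the inference machinery, not its
robustness to real-data violations: amplification and GC bias, damage-driven
mismatches, mapping ambiguity in repeats, contamination, and probe-specific
efficiency variation are all outside the model. Accordingly, on real
libraries the negative-binomial library-size estimate is a lower-bias but not
unbiased extrapolation, and haplogroup conflicts may reflect damage rather
than tree misplacement. The linear fallback deliberately ignores saturation
and so overestimates yield for libraries that merely happen to show no
duplicates at shallow depth.
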