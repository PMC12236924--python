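# Methods

This note documents the statistical procedures, the tunable parameters,
the synthetic-data model behind the test suite, and the design choices
made where the design was genuinely open.

## Outlier flagging

Each QC metric is flagged one-sidedly: low values are bad for yield,
alignment, quantification and complexity metrics (# sequenced reads,
% post-trim, % uniquely aligned, % mapped to exons, # detected genes,
AUC-GBC); high values are bad for contamination metrics (% rRNA,
% adapter, % overrepresented). QC metrics are often skewed, so the null
is built in two steps: `n_bootstrap` (default 1000) resamples of the
reference values, drawn with replacement, give a distribution of means
whose average centers a normal null; the spread is the reference's
sample standard deviation. Warn/fail cutoffs are the `warn_quantile`
(0.1) and `fail_quantile` (0.05) tail quantiles of that null in the
flagged direction. Rationale: a pure sampling-distribution-of-the-mean
null would have spread `σ/√n` and flag nearly every sample; using the
sample spread reproduces the ~10%/5% flag rates the default thresholds
imply, while the bootstrap average stabilizes the center against
outliers in small references.

Numerical conventions: flags use strict inequality, so a value exactly
at a cutoff passes (conservative); a zero-variance reference collapses
both cutoffs to the common value, so identical samples pass and any
deviation fails; absent values produce no flag and exclude the sample
from that metric only; a metric with fewer than five reference values
is dropped with a warning, never fatally. Batches affect only display
(batch-mean overlays); cutoffs are always estimated on the full
reference, because subdividing a reference into batches of a few
samples would make tail quantiles meaningless.

Coverage curves are compared by a two-sample Kolmogorov–Smirnov
statistic: sample curve and per-bin median reference curve are each
normalized to unit mass over the 100 bins, and the statistic is the
maximal absolute gap between their cumulative distributions. The
p-value uses the asymptotic two-sample formula with an effective sample
size of 100 bins per side — a pragmatic convention, since binned
curves have no natural KS sample size; the flag thresholds are then the
same 0.1/0.05 levels applied to that p-value.

## Derived metrics

Percentages follow the read funnel: % post-trim = post-trim/sequenced,
% uniquely aligned = uniquely aligned/post-trim, % rRNA and % mapped to
exons are fractions of uniquely aligned reads — all × 100. The
detected-gene count is the number of genes with non-zero raw counts.
Expression histograms and MSC use log2(CPM + 1), the field's standard
variance-compressing transform; histogram bins are 0.25 wide from 0.

Coverage curves are min–max normalized per sample (both bounds
attained), with bins 1..100 running 5'→3' as produced by the standard
coverage utilities; a constant curve is unscoreable rather than
silently zero. AUC-GBC is the mean normalized bin height, reported on
a 0–100 scale by default (`scale_100=False` gives 0–1) so that a flat
maximal profile reads as 100 and severely 3'-biased libraries fall
into the tens.

## Endpoint scores

- **MSC**: Pearson correlation with the per-gene mean over all samples
  (self included; a leave-one-out mode exists for scatterplots).
  Computed on log2(CPM+1) — raw-count correlation is dominated by a few
  highly expressed genes.
- **UGP**: `log10(min(max(U,1), Lim)) / log10(Lim)`. The floor of 1
  maps a library with no aligned positions to 0, keeping the score in
  [0, 1]. `Lim` defaults to 2×10⁶; deeper protocols should raise it
  (e.g. 5×10⁶), and the choice matters because the log ratio is
  forgiving — UGP only drops below 0.88 when U falls under ~Lim^0.88.
- **CTS**: `mean(M) / (mean(M) + Σ C)` over marker and contaminant
  expression in CPM (units configurable). The default denominator sums
  contaminants, making the score sensitive to any contaminating signal
  even with a long contaminant list; `contaminant_agg="mean"` weighs
  the lists symmetrically. The shipped marker/contaminant lists are
  minimal test defaults — real analyses must supply curated lists.

Labels: low quality iff at least two of the three scores fall strictly
below the cutoff; the low-quality sets are monotone across the 0.88 /
0.90 / 0.91 stringencies by construction.

## Quality classifier

500 trees, feature-subset size 4 (≈√18), unlimited depth — the
conventions of classical random-forest software; all configurable. The
OOB quality score is the out-of-bag vote fraction for "high quality";
scikit-learn averages per-tree class probabilities over OOB trees
rather than hard votes, which coincides with vote fractions up to
numerical noise for fully grown (near-pure-leaf) trees. AUC is computed
from the Mann–Whitney rank statistic (ties count ½). Single-metric
logistic baselines use stratified 5-fold cross-validation with pooled
held-out probabilities — stratification matters because low-quality
prevalence is typically 5–17%. Missing features are median-imputed on
the training data; the medians are stored and reused at prediction.
If an external dataset substitutes zeros for metrics it cannot provide,
supply those columns explicitly rather than leaving them blank, since
zero and absent mean different things.

ALE effects are computed over empirical-quantile grids (40 intervals
for 1-D, 10×10 for 2-D). Per-sample effects use the interval-midpoint
convention, which makes the centering identity `Σ_j f_i(x_ij) = 0`
exact and the average importance a plain mean of absolute effects. The
second-order surface removes both first-order components and imputes
empty grid cells from the nearest populated cell; for additive models
the surface is zero to discretization error. The effect modeled is the
continuous probability-of-high-quality output, not the hard class.
The simplified decision tree (default depth 3) is re-fit with Gini
splitting rather than hard-coded, so its thresholds adapt to the data
while retaining near-forest accuracy.

## Synthetic cohorts

The generator emulates what the pipeline *observes*, not read-level
reality: sequenced reads are log-normal around 3×10⁷ (σ = 0.3 in log
space); funnel fractions are uniform (post-trim 95–99% of sequenced,
uniquely aligned 70–90% of post-trim, mapped-to-exons 50–80% and rRNA
1–5% of uniquely aligned); counts are gamma–Poisson (negative binomial,
dispersion 0.3) over a heavy-tailed expression profile in which 60% of
genes are expressed and 40% are near-silent, so the detected-gene count
responds to depth and complexity; coverage curves are a flat-topped
arch with multiplicative noise; unique positions saturate as
min(0.1 × uniquely aligned, Lim). Defaults are chosen to resemble a
deeply sequenced clinical bulk cohort; `study_like_spec()` fixes 252
samples in 11 batches with ~10% defects.

Archetype effect sizes: `low_depth` divides sequenced reads by 10;
`rrna_contaminated` raises the rRNA fraction to 30–60%;
`degraded_3prime` multiplies coverage by exp(3·t) toward the 3' end;
`low_complexity` raises the expression profile to the 3rd power
(concentrating counts), multiplies unique positions by 0.05 and raises
duplication to 60–85%; `cell_contaminated` mixes 40–60% of an
independent foreign transcriptome — its own expressed-gene subset,
high contaminant genes, silent markers — and carries the mapping-rate
and mitochondrial/ribosomal-protein signature of a mixed population.
Modeling contamination as a profile mixture (rather than shifting a
handful of genes) is deliberate: real cell contamination perturbs the
whole transcriptome, which is what depresses the centroid correlation
alongside the purity score. Every defect also widens the per-gene
expression noise (σ 1.0 vs 0.15 in log space), reflecting that any
technical failure adds noise. Archetypes are composable.

What passing tests on these cohorts do **not** show: the generator has
no isoform structure, no GC/length bias, no batch effects on
expression, no correlated metric noise beyond the funnel, and its
defects are cleanly separated from the clean population. Synthetic
discrimination results (OOB AUCs near 1) are therefore upper bounds;
on real cohorts the same machinery yields lower, overlapping scores.
Structural properties — flag calibration, label monotonicity, score
bounds, determinism — transfer; exact AUC magnitudes do not.

## Problem sizes

Tests and the acceptance script run cohorts of 100–300 samples with
2 000–8 000 genes, 500-tree forests and 37-sample validation cohorts —
sizes chosen so a complete run takes minutes on a single core while
exercising every code path at realistic sample counts.

## Known limitations

Flag directions are one-sided; a two-sided option exists per metric but
no default metric uses it (e.g. % GC deviations in either direction are
not flagged by default). The KS effective-sample-size convention is a
choice, not a derivation. CTS depends strongly on the curated gene
lists. The rRNA panel's regression line is display-only; rRNA flags
come from the % rRNA thresholds. The tool consumes pipeline outputs —
it never runs trimmers, aligners or coverage tools itself.
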