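# Methods

## Model and assumptions

`coexsearch` treats a gene's expression profile across samples as a
noisy affine copy of some latent signature: y = a·s + c + ε with
gene-specific scale a > 0, offset c and i.i.d. Gaussian noise ε.
"Coexpression" is membership in the same latent signature s, and is
operationalized as positive Pearson correlation, which is exactly
invariant to (a, c). The seed group supplies a handful of genes
believed to share s; the signature models are different estimators
of s from those seeds:

- **Mean.** The per-sample arithmetic mean of the seed rows. Under the
  model above it is unbiased for the (average-scale) signature, and
  the noise variance of the estimate falls as 1/k with k seeds. This
  is the default and the most robust choice when the seeds are only
  loosely trusted.
- **Regression.** A polynomial of degree p fit by least squares to
  the seed mean profile over the sample abscissa. The normal-equation
  form is b = (X′X)⁻¹X′Y with the Vandermonde design X (rows 1, x,
  x², …, x^p); the implementation solves the same problem via
  `numpy.linalg.lstsq` (SVD) because the explicit inverse is
  numerically fragile for large p, and raises on rank-deficient
  designs instead of silently regularizing. The fit imposes
  smoothness, which helps when samples are ordered (time courses) and
  the seed mean is still noisy. What is regressed is the seed *mean*
  profile: the regression model is a smoother of the mean model, not
  a different similarity notion.
- **Delegate.** The seed row with the largest range Δ = max − min,
  used verbatim. No averaging artifacts, maximal dynamic range; ties
  go to the earlier seed in list order so the choice is deterministic.
- **Ensemble.** One search per individual seed row; the result is the
  deduplicated union of the per-seed hit sets, each gene keeping its
  best (smallest) p-value. This trades precision for recall: any gene
  resembling *any* seed is reported.

## Search statistic

Similarity is the sample Pearson correlation r computed over
pairwise-complete positions (n ≥ 3 required; genes with fewer
complete pairs, or a constant complete subvector, are skipped and
counted in the log). Significance is the exact two-sided t-test
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, which is the exact
null distribution when profiles are i.i.d. Gaussian. |r| = 1 maps to
p = 0. The threshold is strict (p < threshold). By default only
positively correlated genes are reported, because a coexpression
search looks for profiles that move together; `keep_anticorrelated`
retains both signs.

P-values are deliberately raw: the intended use is an interactive-style
threshold sweep, and published workflows of this kind threshold raw p
(sometimes at values as loose as 0.67, meaningless after correction).
Consequence: with n_bg unrelated background genes, a cut at α admits
about n_bg·α/2 false positives (α/2 because only r > 0 is kept).
Users needing error control can pass `bh_fdr` to additionally require
a Benjamini–Hochberg adjusted p (computed over all scoreable genes,
via statsmodels) below the given level.

## Filtering

The filter statistic is the row range Δ_i; rows with Δ_i < T are
removed before any search, once per pipeline run. T defaults to 0
(no filtering — behaviour is explicit, never implicit). The
population standard deviation y_iσ (divisor N, not N−1) is computed
for the stats report but does not enter the rule. `quantile` mode
sets T to an empirical quantile of the Δ distribution, a scriptable
replacement for choosing T with a slider while watching the data.
Filtering is idempotent and monotone in T; both are property-tested.

## Tiers and heat map

Hits are partitioned by mean expression μ_i into three files/panels.
The cuts are the 1/3 and 2/3 linear-interpolation quantiles of μ_i
among the hit genes; a μ exactly on a boundary goes to the higher
tier, so an all-tied input lands entirely in `high`. Fewer than three
hits cannot define terciles: everything goes to `high` with a
warning. The heat map centres each row on its own mean (no variance
scaling: the red/blue contrast should reflect within-gene deviation,
not inflate flat genes) and uses a diverging red–blue palette, red
above the row mean. The PNG embeds no timestamp or software tag, so
identical inputs give byte-identical files.

## Synthetic data generator

`generate_periodic_matrix` emulates a compact cell-cycle experiment:
group g's latent signature is sin(2π·j/period + φ_g) with the phases
evenly spaced around the circle (successive phase groups peak at
staggered times) and period defaulting to N, one full cycle across
the series. Member rows apply a gene-specific scale a ~ U(0.5, 3),
offset c ~ U(−2, 2) and noise sd 0.3; background genes are i.i.d.
N(0, 1) around a random offset. Defaults: 1000 genes × 18 samples,
five groups of 20. The scale range deliberately spans six-fold so the
scale-independence of the models is actually stressed; the offset
range and unit background variance are inert for correlation-based
search (which is affine-invariant) and only matter for the abundance
tiers. All draws flow from one integer seed through a single
`numpy.random.Generator`; the same seed reproduces the matrix bit
for bit.

What the generator does *not* emulate: mean–variance coupling of
counts, missingness patterns of real arrays, batch structure,
non-sinusoidal or drifting periodicity, and time-shifted (lagged)
coexpression. Tests passing on this generator therefore validate the
machinery — filtering algebra, estimator correctness, test
calibration, set semantics — not biological discovery performance on
real data.

`score_recovery` excludes seed genes from both numerator and
denominator of precision and recall, since recovering the genes the
search was given is not evidence. With zero non-seed hits precision
is undefined; it is reported as 0 with a `defined=False` flag.

## Numerical choices and degenerate inputs

- Row statistics always use the non-missing subset; rows with fewer
  than 2 values are dropped at load time (logged).
- Correlation is clipped into [−1, 1] after the division to absorb
  last-ulp overshoot; a zero denominator (constant subvector) is a
  skip, not an error.
- Result ordering is total and deterministic: ascending p, then
  descending |r|, then input order.
- Duplicate gene IDs are a hard load error (seed lookup must be
  unambiguous); non-numeric cells become missing values rather than
  errors, since real matrices contain blanks and annotations.
- TSV serialization uses shortest round-trip float repr, so
  write-then-read reproduces values exactly.

## Problem sizes

The default test and acceptance workloads use the generator's default
scenario (1000 × 18), a 2000-gene all-null matrix for calibration,
and 50–100 randomized instances for the brute-force consistency
checks; these sizes give stable statistics (binomial standard errors
below a third of each tested margin) while keeping a full run to a
few seconds.

## Known limitations

- No lagged or time-shifted correlation: a target whose profile leads
  or trails the seeds by a phase offset will be missed by design.
- No Spearman or other rank statistics; heavy-tailed noise will
  inflate the Gaussian-exact p-values.
- Raw p thresholds imply a predictable background false-positive rate
  proportional to the matrix size (see above); on large matrices use
  `bh_fdr` or tighten the threshold.
- The ensemble model reports each gene under its best seed only; it
  does not aggregate evidence across seeds.
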