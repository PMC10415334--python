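# Methods

## Deconvolution model

Each bulk sample is modeled as a non-negative mixture of cell-type signature
profiles, `b = Xw + ε` with homoscedastic Gaussian noise per sample. The
coefficients are the cell-type proportions themselves: there is no intercept
(a constant offset would not be a mixture component), and the panel is used
on whatever scale it was assembled on — estimation never rescales it.

Estimation is two-stage empirical Bayes:

1. **First stage (NNLS).** `w ≥ 0` minimizing `‖b − Xw‖²` via
   `scipy.optimize.nnls`. The residual variance is `‖b − Xŵ‖²/(G − k_active)`
   with `k_active` the number of strictly positive coefficients (floored at
   1 df), floored at `1e-8` so noiseless inputs do not divide by zero.
   Per-sample variances are used throughout because bulk samples differ in
   library quality; whether a single shared variance would behave differently
   is an open modeling choice, not something the estimator is sensitive to in
   our tests.
2. **Empirical prior.** Across-sample mean and SD (denominator N−1) of the
   first-stage estimates, per cell type. The SD is floored at `sd_floor`
   (default `1e-3`) so agreement-by-chance between samples cannot produce a
   dogmatic point prior. First-stage estimates are *not* rescaled to sum to
   one before the prior is computed.
3. **EB solve.** Posterior mode under independent Gaussian priors,
   `(XᵀX/σ² + T⁻¹) ŵ = Xᵀb/σ² + T⁻¹μ`. This is the standard
   generalized-ridge closed form implied by the model ingredients (linear
   likelihood, Gaussian prior from the constrained first pass). Negative
   coordinates are truncated to zero *after* the solve rather than solving a
   constrained posterior: truncation is what produces exactly-zero estimates,
   and the per-sample truncation count is reported as a diagnostic.

Two limits pin the estimator's behavior and are asserted in the test suite:
with a very diffuse prior the EB solution equals unconstrained least squares;
with a very tight prior it equals the prior mean. On noiseless mixtures the
pipeline recovers the true proportions to < 1e-3 per coordinate.

Default output is on the raw proportion scale (`renormalize=False`); row-sum
renormalization is available but distorts per-cell-type bias and is off for
all evaluations.

## Panel assembly

`build_panel` standardizes each study's per-cell-type mean profiles gene-wise
(mean 0, variance 1 across that study's cell-type means; zero-variance genes
set to zero) and averages the standardized matrices over studies, so that no
single large study dominates the panel. One consequence worth knowing: exact
gene-wise standardization makes every row sum to zero, hence `X·1 = 0` — the
panel has column rank K−1 and the *overall scale* of the proportions is not
identified by the likelihood alone. The non-negativity constraint of the
first stage and the EB prior resolve this in practice (the evaluation shows
unbiased estimates), but it is why the fit diagnostics carry a
rank-deficiency flag rather than treating rank deficiency as an error.

Marker selection from nucleus-level counts uses a two-part hurdle test of
this package's own construction: a Yates-corrected chi-square on the 2×2
detection table (expressed yes/no × in-type/out-of-type) plus the squared
two-sample t statistic on log-normalized positive counts
(`log(1 + count/total × 10⁴)`), summed and referred to χ² with 2 df. Genes
are ranked per cell type by p-value (ties by log-fold-change), filtered at a
Benjamini–Hochberg FDR within each cell type's family of tests, and the
per-type top lists are unioned. This captures the discrete-plus-continuous
logic of single-cell differential-detection tests in a fully specified form;
it does not reproduce any particular external tool's shrinkage or thresholds.

## Simulation design

Artificial bulk data is generated as `bulk = X Wᵀ + ε`, mixing the
*standardized* panel (the scale a real assembled panel lives on) with
per-sample proportions drawn from independent 4-parameter beta
distributions, rescaled to the simplex. The beta shapes come from method of
moments on a target mean/SD/min/max per cell type. Defaults emulate human
prefrontal cortex: 17 cell types with abundances from 20% (upper-layer
excitatory neurons) down to 1% (a deep-layer excitatory subtype), SD = 25% of
the mean, support [0, mean + 5·SD]. Noise is Gaussian per gene with SD equal
to `noise_sd_fraction` (default 0.05) times the gene's mean absolute
signature value, so the baseline regime is informative but clearly not
noiseless.

Mismatch scenarios: a chosen fraction of bulk cells (exact count, sampled
without replacement) is replaced by uniform draws over the panel's observed
value range — scale-matched nonsense — and/or the additive noise is re-drawn
with its SD multiplied by a factor. The error multiplier needs the clean
signal, so it is applied inside the scenario harness that holds it.

What the generator does *not* emulate: count noise (values are Gaussian, not
negative-binomial), panel-vs-bulk platform effects beyond the two stylized
corruptions, gene–gene correlation beyond the mixture structure, and
cell-type expression heterogeneity across subjects. Passing benchmarks
therefore demonstrate correctness and calibration of the estimator under its
own model, not performance on any particular real dataset.

Benchmark scale: 1,652 panel genes, 17 cell types, 200 samples for the
estimation metrics; 2,000 transcripts, 200 samples, 100 permutations for
calibration. These sizes keep a full run in seconds on one CPU while leaving
Monte-Carlo error well below the decision thresholds.

## Cell-type-specific association

Per transcript the model is
`y = Σₖ wₖβₖ + Σₖ wₖ d δₖ + Zγ + ε`, fitted by OLS with the same design for
every transcript (so the scan is a single batched solve). Choices that
matter:

* **No global intercept.** The proportion main effects span the constant
  (rows of W sum to ~1); an explicit intercept would make the design exactly
  singular for sum-one proportions.
* **Phenotype centered** before forming interactions, so main effects are
  interpretable at the phenotype mean.
* **Covariates fitted jointly, not pre-residualized.** The measured
  covariates and the PC covariates (principal components of the
  covariate-residualized, transcript-standardized expression matrix; sign
  fixed by the largest-magnitude loading) enter the regression as columns
  `Z`. Residualizing only the response and then fitting the proportion terms
  mis-counts residual degrees of freedom whenever the covariate space
  overlaps span(W) — which is guaranteed for mixture data, where the top
  expression PCs *are* proportion variation — and measurably deflates the
  null statistics (permutation λ ≈ 0.95). The joint fit keeps the t
  statistics exactly t-distributed under the null; permutation λ lands at
  1.00–1.01.
* **BH q-values jointly** over all transcript × cell-type tests, with flags
  at FDR 0.1 ("significant") and 0.25 ("suggestive"). After grouping, there
  are fewer tests and q-values are recomputed, never reused.
* **Proportions are not residualized** against covariates; they remain
  interpretable as mixture weights.

Calibration: λ = median(t²)/median(χ²₁), the χ² median computed from the
inverse CDF. `permutation_null` shuffles phenotype labels only (covariates,
PCs and proportions fixed — none of them involve the phenotype, so they are
computed once) and reports λ per cell type per permutation.

The standalone `celltype_association` helper fits the interaction model
without covariates and uses N − 2K residual df; its `ddof_resid` argument
charges extra df if the caller pre-residualized the response.

## Cell-type grouping

PCA treats cell types as variables and genes as observations on the
column-standardized panel; components with eigenvalue > 1 (Kaiser) are
retained — the standard default, since nothing in the grouping's use
dictates a specific count — and varimax-rotated (Kaiser row normalization,
tolerance 1e-6, max 1,000 sweeps; verified against R's `stats::varimax` to
1e-4 on a fixed fixture). Each component's sign is fixed so its dominant
loading is positive, and cell types with *signed* loading > 0.5 on the same
component are merged. The signed rule is deliberate: two unrelated cell
types can share a retained component with loadings of opposite sign
(observed on the test fixture: +0.80/−0.70), and only positively co-loading
— transcriptionally similar — types should merge. A cell type exceeding the
threshold on several components is assigned to its largest loading with a
warning. Merged proportions are summed, not averaged: proportions are mass,
and row sums are preserved exactly.

## Numerical conventions

* All randomness flows from integer seeds through `numpy` generators; the
  CLI and benchmarks derive one independent stream per stage from a seed
  sequence, so adding a stage never perturbs earlier streams.
* PCA/varimax and PC-covariate signs are pinned (largest-magnitude loading
  positive), making reruns bit-identical.
* Correlations of constant columns are reported as undefined and excluded
  from metric averages with a warning.
* Exact zeros (not small values) are what the "zero" metric counts, matching
  the truncation semantics of the estimator.

## Limitations

* The EB closed form assumes independent Gaussian priors; it does not model
  the simplex constraint, and the truncation step is post hoc.
* The hurdle marker test is a simplified stand-in for single-cell
  differential-expression machinery with empirical-Bayes shrinkage.
* The association model contains no covariate × proportion interactions;
  cell-type-specific covariate effects are an extension point.
* Group labels from varimax depend on the retention rule; panels whose
  structure straddles the eigenvalue-1 boundary can group differently under
  small perturbations.
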