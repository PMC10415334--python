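# ebdeconv

Empirical-Bayes estimation of cell-type proportions from bulk transcriptome
data, and cell-type-specific association analysis built on those estimates.

## The problem

Most existing brain gene-expression datasets are *bulk* RNA-seq: each sample
is homogenized tissue mixing neurons, glia and vascular cells in unknown
proportions. Cell-type-specific effects can still be studied statistically if
the per-sample cell-type proportions are known — and those proportions can be
estimated by *deconvolution* against a reference panel of cell-type signature
expression profiles (here, mean expression profiles derived from single-nucleus
RNA-seq). The catch is that brain tissue contains many cell types of low
abundance (interneuron subclasses, microglia, endothelial cells/pericytes at
1–5%), and ordinary regression-based estimators are too noisy for them:
downstream association analyses on badly estimated rare cell types give
unreliable results.

`ebdeconv` is for researchers who want to (re-)use bulk expression data for
cell-type-level analysis: it estimates proportions with a shrinkage estimator
that stays precise for rare cell types, and runs the downstream
cell-type-specific transcriptome-wide association scan (cs-TWAS) with
permutation-based calibration checks.

## The model

For a bulk sample with expression vector **b** over the panel genes, the
mixture model is

    b = X w + ε,   ε ~ N(0, σ² I),   w ≥ 0,

where **X** (genes × cell types) is the reference panel and **w** holds the
cell-type proportions. Estimation is two-stage empirical Bayes:

1. **NNLS stage** — each sample is fitted by non-negative least squares;
   per-sample residual variance σ̂²ᵢ is kept.
2. **Empirical prior** — the across-sample mean **μ** and standard deviation
   **τ** of the NNLS estimates define an independent Gaussian prior per cell
   type, N(μₖ, τₖ²).
3. **EB stage** — each sample is re-fitted as the posterior mode

       ŵ = (XᵀX/σ̂² + T⁻¹)⁻¹ (Xᵀb/σ̂² + T⁻¹μ),   T = diag(τ²),

   a generalized-ridge solve that shrinks toward the across-sample mean;
   negative coordinates are truncated to zero.

The shrinkage pools information across samples, which is exactly what rescues
rare cell types: their estimates are no longer driven by a single sample's
noise. For the association stage, each transcript *y* is regressed on

    yᵢ = Σₖ wᵢₖ βₖ + Σₖ wᵢₖ dᵢ δₖ + covariates + PCs + εᵢ,

where *d* is the (centered) phenotype; the interaction coefficient δₖ carries
the cell-type-k-specific phenotype effect. Calibration is measured by the
genomic inflation factor λ = median(t²)/median(χ²₁) under permuted labels.
Transcriptionally similar cell types can be merged before the scan using PCA
with varimax rotation on the panel (loading > 0.5 on a shared rotated
component).

## Worked example

Everything below is synthetic and self-contained (no downloads). The
`benchmark` module mixes artificial bulk samples from a standardized
1,652-gene, 17-cell-type panel with generalized-beta proportions and 5%
additive noise, estimates the proportions back, and scores them:

```python
from ebdeconv.benchmark import baseline_benchmark

bench = baseline_benchmark(seed=1)
print(bench.eb_table.round(3).to_string())
```

```
          bias   rmse  zero    cor
celltype
EX.UL      0.0  0.002   0.0  0.999
OLI.1      0.0  0.002   0.0  0.999
AST        0.0  0.002   0.0  0.998
...
IN.SV2C    0.0  0.002   0.0  0.920
END.PER    0.0  0.002   0.0  0.901
EX.DL4     0.0  0.002   0.0  0.839
Average    0.0  0.002   0.0  0.969
```

Per cell type: `bias` is the signed mean error of the estimated proportion,
`rmse` its root-mean-square error, `zero` the number of samples estimated at
exactly zero, and `cor` the Pearson correlation between true and estimated
proportions across the 200 samples. Estimates are unbiased and precise on the
proportion scale (RMSE ≈ 0.002), and even the rarest type (EX.DL4, ~1%
abundance) keeps a usable truth-correlation. The same run exposes the fitted
model directly:

```python
res = bench.results            # DeconvolutionResults
res.proportions.data           # samples x cell types, >= 0
res.prior.mean, res.prior.sd   # the empirical prior
res.summary().head(4)
```

```
          prior_mean  prior_sd  mean_estimate  n_zero
celltype
AST           0.1189    0.0279         0.1189       0
END.PER       0.0145    0.0041         0.0145       0
EX.DL1        0.0583    0.0156         0.0583       0
EX.DL2        0.0492    0.0139         0.0492       0
```

The same objects are available from files through the CLI:

```
ebdeconv simulate  --config sim.yaml --out-dir sim/
ebdeconv estimate  --panel sim/panel.tsv --bulk sim/bulk.tsv --out props.tsv
ebdeconv evaluate  --truth sim/true_props.tsv --est props.tsv --out table.tsv
ebdeconv twas      --bulk sim/bulk.tsv --props props.tsv --pheno sim/phenotype.csv --out assoc.tsv
ebdeconv calibrate --bulk sim/bulk.tsv --props props.tsv --pheno sim/phenotype.csv \
                   --n-perm 1000 --seed 1 --out lambdas.tsv
ebdeconv group     --panel sim/panel.tsv --out groups.tsv
```

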