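"""Reproducible benchmark scenarios for the EB estimator and the cs-TWAS.

These functions wire the synthetic-data generators, the estimator and the
scoring metrics into the three standard evaluation designs:

* ``baseline_benchmark`` — artificial bulk mixed from a standardized
  synthetic panel with generalized-beta proportions, scored per cell type
  (bias / RMSE / zeros / correlation) for both the EB and the first-stage
  NNLS estimates;
* ``corruption_benchmark`` — the same design under panel/bulk mismatch
  (a fraction of bulk values replaced by random numbers, or the additive
  error inflated by a multiplier);
* ``calibration_benchmark`` — a null transcript matrix and permuted
  phenotype labels, summarized as genomic inflation factors per cell type
  and permutation.

The mixing panel is produced by `build_panel` from a single synthetic
study, so the artificial bulk lives on the same standardized scale as a
real assembled panel.  All randomness derives from one integer seed via a
seed sequence, one independent stream per stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import permutation_null
from .evaluate import evaluate_estimates
from .model import CellTypeDeconvolution, DeconvolutionResults, ProportionMatrix
from .panel import BulkMatrix, ReferencePanel, StudyProfiles, build_panel
from .simulate import (
    BetaSpec,
    SimulationConfig,
    brain_beta_spec,
    make_bulk,
    make_phenotype,
    make_synthetic_panel,
    simulate_scenario,
)

__all__ = [
    "stage_seeds",
    "standardized_panel",
    "BaselineBenchmark",
    "baseline_benchmark",
    "corruption_benchmark",
    "calibration_benchmark",
]


def stage_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


def standardized_panel(
    n_genes: int,
    celltype_names: list[str],
    markers_per_type: int | None = None,
    marker_effect: float = 5.0,
    seed: int = 0,
) -> ReferencePanel:
    """Synthetic signature panel on the standardized (assembled) scale.

    Generates raw lognormal profiles with planted markers, then runs them
    through `build_panel` as a single study, yielding per-gene
    standardized signature values — the scale a multi-study panel is
    stored on.  By default every gene is a marker for some cell type
    (``markers_per_type = n_genes // K``), as in a panel restricted to
    discriminating genes.
    """
    k = len(celltype_names)
    if markers_per_type is None:
        markers_per_type = n_genes // k
    raw = make_synthetic_panel(
        n_genes, k, markers_per_type=markers_per_type, marker_effect=marker_effect, seed=seed
    )
    raw.data.columns = celltype_names
    return build_panel([StudyProfiles("synthetic", raw.data)])


@dataclass
class BaselineBenchmark:
    """Everything the baseline evaluation produces."""

    panel: ReferencePanel
    spec: BetaSpec
    true_proportions: ProportionMatrix
    bulk: BulkMatrix
    results: DeconvolutionResults
    eb_table: pd.DataFrame
    nnls_table: pd.DataFrame


def baseline_benchmark(
    seed: int,
    n_genes: int = 1652,
    n_samples: int = 200,
    noise_sd_fraction: float = 0.05,
    spec: BetaSpec | None = None,
    fraction_random: float = 0.0,
    error_multiplier: float = 1.0,
) -> BaselineBenchmark:
    """Mix, estimate and score one artificial-bulk scenario.

    The default configuration is the headline design: a 1,652-gene panel
    of 17 brain cell types, 200 bulk samples, additive noise SD at 5% of
    each gene's mean signature magnitude.  Corruption parameters other
    than their defaults turn this into a mismatch scenario.
    """
    if spec is None:
        spec = brain_beta_spec()
    s_panel, s_scn = stage_seeds(seed, 2)
    panel = standardized_panel(n_genes, spec.celltype_names, seed=s_panel)
    cfg = SimulationConfig(
        n_samples=n_samples,
        noise_sd_fraction=noise_sd_fraction,
        fraction_random=fraction_random,
        error_multiplier=error_multiplier,
        seed=s_scn,
    )
    props, bulk = simulate_scenario(panel, spec, cfg)
    results = CellTypeDeconvolution(panel, bulk).fit()
    eb_table = evaluate_estimates(props, results.proportions)
    nnls_table = evaluate_estimates(props, results.nnls_proportions)
    return BaselineBenchmark(panel, spec, props, bulk, results, eb_table, nnls_table)


def corruption_benchmark(
    seed: int,
    fraction_random: float = 0.0,
    error_multiplier: float = 1.0,
    **kwargs,
) -> BaselineBenchmark:
    """Mismatch scenario: same pipeline with bulk corruption applied."""
    return baseline_benchmark(
        seed, fraction_random=fraction_random, error_multiplier=error_multiplier, **kwargs
    )


def calibration_benchmark(
    seed: int,
    n_transcripts: int = 2000,
    n_samples: int = 200,
    n_perm: int = 100,
    n_pcs: int = 6,
    n_covariates: int = 2,
    panel_genes: int = 1652,
) -> pd.DataFrame:
    """Permutation-null lambda table on a synthetic null dataset.

    Builds a panel-gene bulk to estimate proportions from, an independent
    null transcript matrix sharing the same true proportions (no planted
    phenotype effect), and runs `permutation_null`.  Returns the
    permutations x cell-types lambda table.
    """
    spec = brain_beta_spec()
    s_panel, s_scn, s_tpanel, s_tbulk, s_pheno, s_perm = stage_seeds(seed, 6)
    panel = standardized_panel(panel_genes, spec.celltype_names, seed=s_panel)
    cfg = SimulationConfig(n_samples=n_samples, noise_sd_fraction=0.05, seed=s_scn)
    props, bulk = simulate_scenario(panel, spec, cfg)
    results = CellTypeDeconvolution(panel, bulk).fit()

    t_panel = standardized_panel(n_transcripts, spec.celltype_names, seed=s_tpanel)
    transcripts = make_bulk(t_panel, props, noise_sd_fraction=0.05, seed=s_tbulk)
    pheno, transcripts = make_phenotype(
        props, transcripts, seed=s_pheno, n_covariates=n_covariates
    )
    return permutation_null(
        transcripts, results.proportions, pheno, n_perm=n_perm, seed=s_perm, n_pcs=n_pcs
    )
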