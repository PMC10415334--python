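"""Synthetic data generators: panels, mixtures, corruptions, nuclei, phenotypes.

Artificial bulk data is built from a reference panel and per-sample
cell-type proportions drawn from a generalized (4-parameter) beta
distribution: each cell type's proportion lives on ``[min, max]`` with
shape parameters obtained by method of moments from a target mean and SD.
Gaussian noise with per-gene SD proportional to the gene's mean panel
magnitude is added, and two corruption scenarios — replacing a fraction of
bulk cells with scale-matched random values, and inflating the additive
noise by a multiplier — emulate mismatch between panel and bulk data.

Everything here is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ProportionMatrix
from .panel import BulkMatrix, NucleusCounts, ReferencePanel

__all__ = [
    "BetaSpec",
    "SimulationConfig",
    "brain_beta_spec",
    "default_beta_spec",
    "BRAIN_CELLTYPES",
    "draw_proportions",
    "make_bulk",
    "corrupt_bulk",
    "make_synthetic_panel",
    "make_synthetic_nuclei",
    "make_phenotype",
    "simulate_scenario",
]

# Default 17-cell-type abundance profile for human prefrontal cortex:
# upper-layer excitatory neurons and oligodendrocytes dominant, astrocytes
# next, interneuron subclasses / OPC / microglia / endothelial-pericyte at
# low abundance.  Values are artifact defaults on the proportion scale.
BRAIN_CELLTYPES: dict[str, float] = {
    "EX.UL": 0.20,
    "OLI.1": 0.17,
    "AST": 0.12,
    "EX.NRGN": 0.07,
    "EX.DL1": 0.06,
    "EX.DL2": 0.05,
    "OLI.2": 0.05,
    "OPC": 0.05,
    "IN.VIP": 0.04,
    "IN.PV": 0.04,
    "MGL": 0.04,
    "IN.SST": 0.03,
    "EX.DL3": 0.025,
    "EX.NRG1": 0.02,
    "IN.SV2C": 0.015,
    "END.PER": 0.015,
    "EX.DL4": 0.01,
}


@dataclass
class BetaSpec:
    """Per-cell-type 4-parameter beta specification on the proportion scale.

    For each cell type ``k`` the proportion is drawn on ``[min_k, max_k]``
    with shapes from the method of moments: with ``m = (mu-a)/(b-a)`` and
    ``s^2 = sd^2/(b-a)^2``,

        alpha = m (m(1-m)/s^2 - 1),   beta = (1-m) (m(1-m)/s^2 - 1).

    The constructor rejects specs whose implied shapes are not both
    positive (moment-infeasible: ``s^2 >= m(1-m)``).
    """

    celltype_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    alpha: np.ndarray = field(init=False)
    beta: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.min = np.asarray(self.min, dtype=float)
        self.max = np.asarray(self.max, dtype=float)
        k = len(self.celltype_names)
        for name, arr in (("mean", self.mean), ("sd", self.sd), ("min", self.min), ("max", self.max)):
            if arr.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
        if np.any(self.min >= self.max):
            bad = self.celltype_names[int(np.argmax(self.min >= self.max))]
            raise ValueError(f"min >= max for cell type {bad!r}")
        if np.any((self.mean < self.min) | (self.mean > self.max)):
            bad = self.celltype_names[int(np.argmax((self.mean < self.min) | (self.mean > self.max)))]
            raise ValueError(f"mean outside [min, max] for cell type {bad!r}")
        if np.any(self.sd <= 0):
            raise ValueError("sd must be positive")
        span = self.max - self.min
        m = (self.mean - self.min) / span
        s2 = self.sd**2 / span**2
        nu = m * (1 - m) / s2 - 1  # alpha + beta
        self.alpha = m * nu
        self.beta = (1 - m) * nu
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            bad = self.celltype_names[int(np.argmax((self.alpha <= 0) | (self.beta <= 0)))]
            raise ValueError(
                f"moment-infeasible spec for cell type {bad!r}: need sd^2 < m(1-m)(max-min)^2"
            )


def brain_beta_spec(cv: float = 0.25) -> BetaSpec:
    """The default 17-cell-type proportion distribution (brain-like).

    Each type's SD is ``cv`` times its mean; the support is
    ``[0, min(1, mean + 5 sd)]``.
    """
    names = list(BRAIN_CELLTYPES)
    mu = np.array([BRAIN_CELLTYPES[n] for n in names])
    sd = cv * mu
    return BetaSpec(names, mu, sd, np.zeros_like(mu), np.minimum(1.0, mu + 5 * sd))


def default_beta_spec(celltype_names: list[str], cv: float = 0.25) -> BetaSpec:
    """Brain-like abundance profile mapped onto arbitrary cell-type names.

    The first ``K`` abundances of the default brain profile (largest
    first) are renormalized to sum to one and assigned to the given names
    in order.  For more than 17 cell types an explicit `BetaSpec` is
    required.
    """
    k = len(celltype_names)
    abundances = sorted(BRAIN_CELLTYPES.values(), reverse=True)
    if k > len(abundances):
        raise ValueError(f"no default abundance profile for {k} > 17 cell types")
    mu = np.array(abundances[:k])
    mu = mu / mu.sum()
    sd = cv * mu
    return BetaSpec(list(celltype_names), mu, sd, np.zeros_like(mu), np.minimum(1.0, mu + 5 * sd))


@dataclass
class SimulationConfig:
    """Baseline and corruption-scenario settings for artificial bulk data."""

    n_samples: int = 200
    noise_sd_fraction: float = 0.05
    fraction_random: float = 0.0
    error_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.fraction_random <= 1.0:
            raise ValueError("fraction_random must be in [0, 1]")
        if self.error_multiplier < 1.0:
            raise ValueError("error_multiplier must be >= 1")


def draw_proportions(spec: BetaSpec, n_samples: int, seed: int) -> ProportionMatrix:
    """Draw per-sample proportions from independent generalized betas.

    Each cell type is drawn independently on its own ``[min, max]`` support;
    every sample's vector is then rescaled to sum to one (proportions live
    on the simplex).
    """
    rng = np.random.default_rng(seed)
    k = len(spec.celltype_names)
    raw = spec.min + (spec.max - spec.min) * rng.beta(spec.alpha, spec.beta, size=(n_samples, k))
    w = raw / raw.sum(axis=1, keepdims=True)
    idx = [f"sample_{i + 1}" for i in range(n_samples)]
    return ProportionMatrix(pd.DataFrame(w, index=idx, columns=spec.celltype_names))


def _noise_sd_per_gene(panel: ReferencePanel, noise_sd_fraction: float) -> np.ndarray:
    """Per-gene noise SD: fraction of the gene's mean absolute panel value."""
    return noise_sd_fraction * np.abs(panel.values).mean(axis=1)


def make_bulk(
    panel: ReferencePanel,
    proportions: ProportionMatrix,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
) -> BulkMatrix:
    """Mix panel columns by the given proportions and add Gaussian noise.

    ``bulk(g, i) = sum_k X(g,k) w(i,k) + eps(g,i)`` with
    ``eps ~ Normal(0, (noise_sd_fraction * mean_k |X(g,k)|)^2)``,
    independent across genes and samples.
    """
    if set(panel.celltype_names) != set(proportions.celltype_names):
        raise ValueError("panel and proportions have different cell-type sets")
    w = proportions.data[panel.celltype_names].to_numpy()
    signal = panel.values @ w.T
    rng = np.random.default_rng(seed)
    sd = _noise_sd_per_gene(panel, noise_sd_fraction)
    noise = rng.normal(0.0, 1.0, size=signal.shape) * sd[:, None]
    return BulkMatrix(
        pd.DataFrame(signal + noise, index=panel.gene_ids, columns=proportions.sample_ids)
    )


def corrupt_bulk(
    bulk: BulkMatrix,
    fraction_random: float,
    error_multiplier: float = 1.0,
    panel_value_range: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    clean_signal: np.ndarray | None = None,
    noise_sd: np.ndarray | None = None,
) -> BulkMatrix:
    """Apply the mismatch scenarios to a bulk matrix.

    ``error_multiplier > 1`` re-generates the additive noise with its SD
    scaled by the multiplier, which requires the clean (noiseless) signal
    and the per-gene baseline noise SD — `simulate_scenario` holds both.
    Then an exact ``round(fraction_random * cells)`` subset of cells,
    chosen without replacement, is replaced by uniform draws over
    ``panel_value_range`` (scale-matched nonsense values).
    """
    if not 0.0 <= fraction_random <= 1.0:
        raise ValueError("fraction_random must be in [0, 1]")
    if error_multiplier < 1.0:
        raise ValueError("error_multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    values = bulk.values.copy()
    if error_multiplier > 1.0:
        if clean_signal is None or noise_sd is None:
            raise ValueError(
                "error_multiplier > 1 needs clean_signal and noise_sd "
                "(the corruption re-draws the additive noise)"
            )
        noise = rng.normal(0.0, 1.0, size=values.shape) * noise_sd[:, None]
        values = clean_signal + error_multiplier * noise
    n_cells = values.size
    n_replace = int(round(fraction_random * n_cells))
    if n_replace:
        flat = rng.choice(n_cells, size=n_replace, replace=False)
        lo, hi = panel_value_range
        values.flat[flat] = rng.uniform(lo, hi, size=n_replace)
    return BulkMatrix(pd.DataFrame(values, index=bulk.gene_ids, columns=bulk.sample_ids))


def make_synthetic_panel(
    n_genes: int,
    n_celltypes: int,
    markers_per_type: int = 20,
    marker_effect: float = 5.0,
    seed: int = 0,
) -> ReferencePanel:
    """Synthetic signature matrix with planted marker blocks.

    Baseline expression is lognormal per gene (shared across cell types);
    each type's dedicated block of ``markers_per_type`` genes is multiplied
    by ``marker_effect`` in that type only.
    """
    if n_genes < n_celltypes * markers_per_type:
        raise ValueError(
            f"n_genes={n_genes} < n_celltypes*markers_per_type="
            f"{n_celltypes * markers_per_type}"
        )
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    x = np.tile(base[:, None], (1, n_celltypes))
    for k in range(n_celltypes):
        rows = slice(k * markers_per_type, (k + 1) * markers_per_type)
        x[rows, k] *= marker_effect
    genes = [f"gene_{g + 1}" for g in range(n_genes)]
    types = [f"celltype_{k + 1}" for k in range(n_celltypes)]
    return ReferencePanel(pd.DataFrame(x, index=genes, columns=types))


def make_synthetic_nuclei(
    truth: ReferencePanel,
    nuclei_per_type: int,
    depth: int,
    seed: int = 0,
) -> NucleusCounts:
    """Multinomial nucleus-level counts from per-type expression profiles.

    Each nucleus of type ``k`` receives ``depth`` UMIs multinomially over
    genes with probabilities proportional to column ``k`` of ``truth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    x = truth.values
    if np.any(x < 0):
        raise ValueError("expression profiles must be non-negative")
    probs = x / x.sum(axis=0, keepdims=True)
    cols = []
    labels = []
    for k, name in enumerate(truth.celltype_names):
        cols.append(rng.multinomial(depth, probs[:, k], size=nuclei_per_type).T)
        labels.extend([name] * nuclei_per_type)
    counts = np.concatenate(cols, axis=1)
    nucleus_ids = [f"nucleus_{i + 1}" for i in range(counts.shape[1])]
    return NucleusCounts(
        pd.DataFrame(counts, index=truth.gene_ids, columns=nucleus_ids), labels
    )


def make_phenotype(
    proportions: ProportionMatrix,
    bulk: BulkMatrix,
    effect_spec: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    n_covariates: int = 0,
    covariate_effect_fraction: float = 0.1,
) -> tuple[pd.DataFrame, BulkMatrix]:
    """Balanced binary phenotype, optional covariates and planted effects.

    ``effect_spec`` maps transcript ID -> {cell type: delta}; for each entry
    ``delta * d_i * w(i, k)`` is added to that transcript in every sample,
    planting a cell-type-specific phenotype interaction (``d`` is the
    balanced 0/1 label).  Transcripts not named are untouched.  Optional
    standard-normal covariates additively shift every transcript with
    per-transcript coefficients scaled to ``covariate_effect_fraction`` of
    the transcript's mean magnitude.

    Returns the phenotype/covariate table (indexed by sample, column
    ``phenotype`` plus ``cov1..covC``) and the modified bulk matrix.
    """
    rng = np.random.default_rng(seed)
    n = len(bulk.sample_ids)
    d = np.zeros(n)
    d[rng.permutation(n)[: n // 2]] = 1.0
    values = bulk.values.copy()
    table = pd.DataFrame({"phenotype": d}, index=pd.Index(bulk.sample_ids, name="sample_id"))
    for c in range(n_covariates):
        cov = rng.normal(size=n)
        scale = covariate_effect_fraction * np.abs(values).mean(axis=1)
        beta = rng.normal(size=values.shape[0]) * scale
        values += np.outer(beta, cov)
        table[f"cov{c + 1}"] = cov
    if effect_spec:
        missing = [t for t in effect_spec if t not in set(bulk.gene_ids)]
        if missing:
            raise ValueError(f"unknown transcripts in effect_spec: {', '.join(missing)}")
        gene_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
        w = proportions.data.loc[bulk.sample_ids]
        for transcript, effects in effect_spec.items():
            for celltype, delta in effects.items():
                if celltype not in w.columns:
                    raise ValueError(f"unknown cell type {celltype!r} in effect_spec")
                values[gene_pos[transcript]] += delta * d * w[celltype].to_numpy()
    out = BulkMatrix(pd.DataFrame(values, index=bulk.gene_ids, columns=bulk.sample_ids))
    return table, out


def simulate_scenario(
    panel: ReferencePanel,
    spec: BetaSpec,
    config: SimulationConfig,
) -> tuple[ProportionMatrix, BulkMatrix]:
    """Generate one full scenario: proportions, noisy bulk, corruptions.

    Holds the clean signal so the error-multiplier corruption can re-draw
    the additive noise at the scaled SD; the random-replacement corruption
    draws uniformly over the panel's observed value range.
    """
    ss = np.random.SeedSequence(config.seed)
    s_props, s_bulk, s_corrupt = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    props = draw_proportions(spec, config.n_samples, seed=s_props)
    bulk = make_bulk(panel, props, config.noise_sd_fraction, seed=s_bulk)
    if config.fraction_random > 0 or config.error_multiplier > 1:
        w = props.data[panel.celltype_names].to_numpy()
        clean = panel.values @ w.T
        sd = _noise_sd_per_gene(panel, config.noise_sd_fraction)
        rng_range = (float(panel.values.min()), float(panel.values.max()))
        bulk = corrupt_bulk(
            bulk,
            config.fraction_random,
            config.error_multiplier,
            panel_value_range=rng_range,
            seed=s_corrupt,
            clean_signal=clean,
            noise_sd=sd,
        )
    return props, bulk
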