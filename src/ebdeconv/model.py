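"""Empirical-Bayes estimation of cell-type proportions from bulk expression.

The deconvolution model for one bulk sample is the linear mixture

    b = X w + e,    e ~ Normal(0, sigma^2 I),  w >= 0,

where ``X`` is the reference panel (genes x cell types) and ``w`` holds the
cell-type proportions.  Estimation is a two-stage empirical-Bayes (EB)
procedure:

1. each sample is fitted by non-negative least squares (NNLS), giving
   first-stage proportion estimates and a residual noise variance;
2. the across-sample mean and standard deviation of the NNLS estimates form
   an independent Gaussian prior per cell type;
3. each sample is re-fitted as the posterior mode under that prior
   (a generalized ridge solve), and negative coordinates are truncated to
   zero.

The shrinkage toward the across-sample mean is what makes estimates for
multiple low-abundance cell types precise: the prior pools information
across samples, so a rare cell type's estimate is no longer driven by that
one sample's noise alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .panel import BulkMatrix, ReferencePanel, _check_finite, _check_unique, align_genes

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionMatrix",
    "PriorSpec",
    "FitDiagnostics",
    "fit_nnls",
    "estimate_prior",
    "fit_eb",
    "estimate_proportions",
    "CellTypeDeconvolution",
    "DeconvolutionResults",
]

SIGMA2_FLOOR = 1e-8  # noiseless fixtures otherwise divide by zero
SD_FLOOR_DEFAULT = 1e-3


class ProportionMatrix:
    """Samples x cell-types matrix of non-negative proportions."""

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data)
        _check_unique(data.index, "sample IDs")
        _check_unique(data.columns, "cell-type names")
        values = data.to_numpy(dtype=float)
        _check_finite(values, "proportions")
        if np.any(values < 0):
            i, k = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative proportion at sample {data.index[i]!r}, "
                f"cell type {data.columns[k]!r}"
            )
        self.data = data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def celltype_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, k = self.shape
        return f"ProportionMatrix({n} samples x {k} cell types)"


@dataclass
class PriorSpec:
    """Independent Gaussian prior per cell type (mean, SD), SD floored."""

    celltype_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("prior mean and sd must be 1-D of equal length")
        if len(self.celltype_names) != self.mean.size:
            raise ValueError("prior length does not match cell-type names")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.sd))):
            raise ValueError("prior parameters must be finite")
        if np.any(self.mean < 0):
            raise ValueError("prior means must be non-negative")
        if np.any(self.sd <= 0):
            raise ValueError("prior SDs must be strictly positive (apply a floor)")


@dataclass
class FitDiagnostics:
    """Per-sample noise variances, truncation counts and conditioning flags."""

    sample_ids: list[str]
    sigma2: np.ndarray  # per-sample residual variance from the NNLS stage
    n_truncated: np.ndarray  # EB coordinates truncated to zero, per sample
    rank_deficient: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sigma2": self.sigma2, "n_truncated": self.n_truncated},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def fit_nnls(panel: ReferencePanel, bulk_sample: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares fit of one bulk sample on the panel.

    Returns ``(w, residual_variance)`` where ``w >= 0`` minimizes
    ``||b - Xw||^2`` and the residual variance uses ``G - k_active``
    degrees of freedom, ``k_active`` being the number of strictly positive
    coefficients (floored at 1 df).
    """
    x = panel.values
    b = np.asarray(bulk_sample, dtype=float)
    if b.shape != (x.shape[0],):
        raise ValueError(f"bulk sample has length {b.size}, panel has {x.shape[0]} genes")
    w, rnorm = _scipy_nnls(x, b)
    k_active = int(np.sum(w > 0))
    df = max(x.shape[0] - k_active, 1)
    return w, float(rnorm**2) / df


def estimate_prior(
    nnls_estimates: ProportionMatrix, sd_floor: float = SD_FLOOR_DEFAULT
) -> PriorSpec:
    """Empirical prior: across-sample mean and SD of first-stage estimates.

    SDs use the N-1 denominator and are floored at ``sd_floor`` so the
    prior never degenerates to a point mass.
    """
    if nnls_estimates.shape[0] < 2:
        raise ValueError("prior estimation needs at least 2 samples (SD undefined)")
    if sd_floor <= 0:
        raise ValueError("sd_floor must be positive")
    v = nnls_estimates.values
    mean = v.mean(axis=0)
    sd = np.maximum(v.std(axis=0, ddof=1), sd_floor)
    return PriorSpec(nnls_estimates.celltype_names, mean, sd)


def fit_eb(
    panel: ReferencePanel,
    bulk_sample: np.ndarray,
    prior: PriorSpec,
    sigma2: float,
    return_raw: bool = False,
) -> np.ndarray:
    """Empirical-Bayes (posterior-mode) proportion estimate for one sample.

    Solves the generalized-ridge normal equations

        (X'X / sigma^2 + T^-1) w = X'b / sigma^2 + T^-1 mu,

    with ``T = diag(prior.sd^2)`` and ``mu = prior.mean`` — the posterior
    mode under independent Gaussian priors and Gaussian noise — then
    truncates negative coordinates to zero.  With ``return_raw`` the
    pre-truncation solution is returned instead.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = panel.values
    b = np.asarray(bulk_sample, dtype=float)
    t_inv = 1.0 / prior.sd**2
    a = x.T @ x / sigma2 + np.diag(t_inv)
    rhs = x.T @ b / sigma2 + t_inv * prior.mean
    try:
        w = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:  # cannot occur with floored sd, finite sigma2
        raise ValueError(f"singular EB system: {exc}") from exc
    return w if return_raw else np.maximum(w, 0.0)


def estimate_proportions(
    panel: ReferencePanel,
    bulk: BulkMatrix,
    sd_floor: float = SD_FLOOR_DEFAULT,
    renormalize: bool = False,
) -> tuple[ProportionMatrix, FitDiagnostics]:
    """Full two-stage EB pipeline over all bulk samples.

    Convenience function; equivalent to
    ``CellTypeDeconvolution(panel, bulk).fit(...)`` and returning the
    results object's proportions and diagnostics.
    """
    res = CellTypeDeconvolution(panel, bulk).fit(sd_floor=sd_floor, renormalize=renormalize)
    return res.proportions, res.diagnostics


class CellTypeDeconvolution:
    """Deconvolution model binding a reference panel to a bulk matrix.

    Parameters
    ----------
    panel : ReferencePanel
        Genes x cell-types signature matrix (the design matrix).
    bulk : BulkMatrix
        Genes x samples expression matrix.  Gene sets are intersected and
        aligned at construction; at least two samples are required (the
        empirical prior needs an across-sample SD).

    Examples
    --------
    >>> res = CellTypeDeconvolution(panel, bulk).fit()
    >>> res.proportions.data          # samples x cell types, >= 0
    >>> res.prior.mean, res.prior.sd  # empirical prior
    """

    def __init__(self, panel: ReferencePanel, bulk: BulkMatrix):
        self.panel, self.bulk = align_genes(panel, bulk)
        if self.bulk.shape[1] < 2:
            raise ValueError("deconvolution needs at least 2 bulk samples")
        self.rank_deficient = (
            np.linalg.matrix_rank(self.panel.values) < self.panel.shape[1]
        )
        if self.rank_deficient:
            logger.warning("reference panel is numerically rank-deficient")

    def fit_nnls_only(self) -> tuple[ProportionMatrix, np.ndarray]:
        """First-stage NNLS estimates and per-sample residual variances."""
        x = self.panel
        n = self.bulk.shape[1]
        k = x.shape[1]
        w = np.empty((n, k))
        sigma2 = np.empty(n)
        for i in range(n):
            w[i], sigma2[i] = fit_nnls(x, self.bulk.values[:, i])
        props = ProportionMatrix(
            pd.DataFrame(w, index=self.bulk.sample_ids, columns=x.celltype_names)
        )
        return props, np.maximum(sigma2, SIGMA2_FLOOR)

    def fit(
        self,
        sd_floor: float = SD_FLOOR_DEFAULT,
        renormalize: bool = False,
    ) -> "DeconvolutionResults":
        """Run NNLS -> empirical prior -> per-sample EB shrinkage.

        Each sample's EB solve uses that sample's own NNLS residual
        variance (floored at ``1e-8``).  With ``renormalize`` every row
        with positive sum is rescaled to sum to one (off by default: the
        raw scale is what the evaluation metrics are defined on).
        """
        nnls_props, sigma2 = self.fit_nnls_only()
        prior = estimate_prior(nnls_props, sd_floor=sd_floor)
        n, k = nnls_props.shape
        w = np.empty((n, k))
        n_trunc = np.empty(n, dtype=int)
        for i in range(n):
            raw = fit_eb(self.panel, self.bulk.values[:, i], prior, sigma2[i], return_raw=True)
            n_trunc[i] = int(np.sum(raw < 0))
            w[i] = np.maximum(raw, 0.0)
        if renormalize:
            sums = w.sum(axis=1, keepdims=True)
            np.divide(w, sums, out=w, where=sums > 0)
        props = ProportionMatrix(
            pd.DataFrame(w, index=self.bulk.sample_ids, columns=self.panel.celltype_names)
        )
        diag = FitDiagnostics(self.bulk.sample_ids, sigma2, n_trunc, self.rank_deficient)
        return DeconvolutionResults(self, props, nnls_props, prior, diag)


class DeconvolutionResults:
    """Fitted proportions plus the prior and diagnostics that produced them."""

    def __init__(
        self,
        model: CellTypeDeconvolution,
        proportions: ProportionMatrix,
        nnls_proportions: ProportionMatrix,
        prior: PriorSpec,
        diagnostics: FitDiagnostics,
    ):
        self.model = model
        self.proportions = proportions
        self.nnls_proportions = nnls_proportions
        self.prior = prior
        self.diagnostics = diagnostics

    def summary(self) -> pd.DataFrame:
        """Per-cell-type summary: prior, mean estimate, zero counts."""
        est = self.proportions.values
        return pd.DataFrame(
            {
                "prior_mean": self.prior.mean,
                "prior_sd": self.prior.sd,
                "mean_estimate": est.mean(axis=0),
                "n_zero": (est == 0).sum(axis=0),
            },
            index=pd.Index(self.proportions.celltype_names, name="celltype"),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, k = self.proportions.shape
        return f"DeconvolutionResults({n} samples x {k} cell types)"
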