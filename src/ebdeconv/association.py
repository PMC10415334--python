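"""Cell-type-specific transcriptome-wide association (cs-TWAS).

Given estimated cell-type proportions ``w`` and a phenotype ``d``, the
association model for one transcript ``y`` over samples ``i`` is the
interaction regression

    y_i = sum_k w_ik beta_k + sum_k w_ik d_i delta_k + e_i,

with no global intercept (the proportion main effects span it when rows
sum to one) and the phenotype centered so main effects are interpretable
at the phenotype mean.  The interaction coefficient ``delta_k`` carries
the cell-type-k-specific phenotype effect; fitting all cell types jointly
avoids omitted-variable confounding between correlated proportions.

Measured covariates are regressed out of expression, and principal
components of the covariate-residualized matrix serve as additional
covariates absorbing unmeasured variation; in the per-transcript fits the
covariate and PC columns enter the regression jointly with the
proportion terms, so residual degrees of freedom stay exact.  Test
calibration is assessed by the genomic inflation factor

    lambda = median(t^2) / median(chi-square_1),

computed per cell type over transcripts, under permutations of the
phenotype labels; lambda near one means the null p-values are accurate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ProportionMatrix
from .panel import BulkMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "residualize",
    "pca_covariates",
    "celltype_association",
    "run_twas",
    "compute_lambda",
    "permutation_null",
    "CellTypeAssociation",
    "AssociationResults",
]

_ORTHO_TOL = 1e-8


def _design_with_intercept(covariates: np.ndarray) -> np.ndarray:
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] == 1 and c.size and c.shape[1] != 1:
        c = c.T if c.shape[0] != c.shape[1] else c
    return np.column_stack([np.ones(c.shape[0]), c]) if c.size else np.ones((c.shape[0], 1))


def residualize(matrix: np.ndarray | pd.DataFrame, covariates: np.ndarray | pd.DataFrame | None) -> np.ndarray | pd.DataFrame:
    """Replace each transcript row by its least-squares residuals.

    Residuals are from regressing the row on an intercept plus the given
    covariate columns (samples x C); the output is orthogonal to every
    covariate column to within 1e-8.  Collinear covariates are rejected by
    name.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    y = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    n = y.shape[1]
    if covariates is None or (hasattr(covariates, "shape") and np.asarray(covariates).size == 0):
        design = np.ones((n, 1))
        names = ["intercept"]
    else:
        cov_df = pd.DataFrame(covariates)
        design = np.column_stack([np.ones(n), cov_df.to_numpy(dtype=float)])
        names = ["intercept"] + [str(c) for c in cov_df.columns]
    if design.shape[0] != n:
        raise ValueError("covariate rows do not match the number of samples")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(names[j])
        raise ValueError(f"collinear covariate columns: {', '.join(bad)}")
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    resid = y - (design @ coef).T
    if is_df:
        return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)
    return resid


def pca_covariates(residualized_bulk: np.ndarray | pd.DataFrame, n_components: int) -> np.ndarray:
    """Principal-component scores over samples of a residualized matrix.

    Each transcript row is standardized first; the scores of the top
    ``n_components`` components (samples x R) are returned, with each
    component's sign fixed so its largest-magnitude transcript loading is
    positive (bit-reproducible across runs).
    """
    y = np.asarray(residualized_bulk, dtype=float)
    g, n = y.shape
    if n_components >= min(g, n):
        raise ValueError(f"n_components={n_components} must be < min(G, N)={min(g, n)}")
    sd = y.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (y - y.mean(axis=1, keepdims=True)) / sd
    # samples as observations, transcripts as variables
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _interaction_design(
    proportions: ProportionMatrix, phenotype: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Design [W | W * centered phenotype]; all-zero cell types dropped."""
    w = proportions.values
    names = proportions.celltype_names
    keep = ~np.all(w == 0, axis=0)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("dropping all-zero cell types: %s", ", ".join(dropped))
    w = w[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    d = np.asarray(phenotype, dtype=float)
    if d.std() == 0:
        raise ValueError("phenotype has no variance")
    dc = d - d.mean()
    design = np.column_stack([w, w * dc[:, None]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient interaction design (collinear proportions)")
    return design, names


def _batched_interaction_fit(
    y: np.ndarray,
    design: np.ndarray,
    k: int,
    ddof_resid: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of many transcripts on one shared design matrix.

    Returns (delta, se, t, p, dof) for the LAST ``k`` design columns (the
    interaction coefficients) of every transcript; ``y`` is transcripts x
    samples.  ``ddof_resid`` charges extra residual degrees of freedom for
    directions removed from ``y`` outside the design.
    """
    n = design.shape[1]
    dof = y.shape[1] - n - ddof_resid
    if dof < 1:
        raise ValueError(f"non-positive residual degrees of freedom ({dof})")
    dtd_inv = np.linalg.inv(design.T @ design)
    coef = dtd_inv @ design.T @ y.T  # ncol x G
    resid = y.T - design @ coef
    sigma2 = (resid**2).sum(axis=0) / dof
    diag = np.diag(dtd_inv)[n - k:]
    delta = coef[n - k:].T  # G x K
    se = np.sqrt(np.outer(sigma2, diag))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return delta, se, t, p, dof


def celltype_association(
    y: np.ndarray,
    proportions: ProportionMatrix,
    phenotype: np.ndarray,
    ddof_resid: int = 0,
) -> pd.DataFrame:
    """Interaction-model association of one transcript with the phenotype.

    Fits the single joint model described in the module docstring and
    returns one row per cell type with the interaction estimate, its
    standard error, the t statistic and the two-sided p-value (residual
    df ``N - 2K - ddof_resid``; pass ``ddof_resid`` to account for
    degrees of freedom consumed by a prior residualization of ``y``).
    Cell types whose estimated proportions are all zero are reported as
    NA rows.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 2 * len(proportions.celltype_names) + 1:
        raise ValueError("too few samples for the interaction model")
    design, fitted_names = _interaction_design(proportions, phenotype)
    delta, se, t, p, _ = _batched_interaction_fit(
        y[None, :], design, len(fitted_names), ddof_resid
    )
    out = pd.DataFrame(
        {"estimate": delta[0], "se": se[0], "t": t[0], "p": p[0]},
        index=pd.Index(fitted_names, name="celltype"),
    )
    return out.reindex(proportions.celltype_names)  # NA rows for dropped types


def compute_lambda(t_stats: np.ndarray) -> float:
    """Genomic inflation factor from a vector of t statistics.

    ``lambda = median(t^2) / m0`` with ``m0`` the median of the
    chi-square distribution with 1 df (computed via the inverse CDF, not
    hard-coded).
    """
    t = np.asarray(t_stats, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite test statistics")
    return float(np.median(t**2) / stats.chi2.ppf(0.5, df=1))


def _twas_setup(
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    phenotype_table: pd.DataFrame,
    n_pcs: int,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Common covariate handling for the scan and the permutation null.

    Computes the PC covariates from the covariate-residualized expression
    matrix, then assembles the joint per-transcript design
    ``[covariates | PCs | W | W*d]``.  There is no explicit intercept:
    the proportion main effects span the constant (rows of ``W`` sum to
    ~1), and adding one would make the design exactly singular for
    sum-one proportions.  Fitting covariates jointly with the proportion
    terms (rather than pre-residualizing the response alone) keeps the
    residual degrees of freedom exact even when the covariate space
    overlaps the span of the proportions, so null t statistics follow
    their nominal t distribution.
    """
    samples = bulk.sample_ids
    if list(phenotype_table.index) != samples:
        try:
            phenotype_table = phenotype_table.loc[samples]
        except KeyError as exc:
            raise ValueError(f"phenotype table is missing samples: {exc}") from exc
    props = ProportionMatrix(proportions.data.loc[samples])
    d = phenotype_table["phenotype"].to_numpy(dtype=float)
    covars = phenotype_table.drop(columns=["phenotype"])

    y = bulk.values
    blocks = []
    if covars.shape[1]:
        blocks.append(covars.to_numpy(dtype=float))
    if n_pcs > 0:
        resid = residualize(y, covars if covars.shape[1] else None)
        blocks.append(pca_covariates(resid, n_pcs))
    inter_design, fitted_names = _interaction_design(props, d)
    covariate_block = np.column_stack(blocks) if blocks else np.empty((len(samples), 0))
    design = np.column_stack([covariate_block, inter_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (covariates collinear with proportions)")
    return y, design, fitted_names, len(fitted_names)


def run_twas(
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    phenotype_table: pd.DataFrame,
    n_pcs: int = 6,
    fdr_levels: tuple[float, ...] = (0.1, 0.25),
) -> pd.DataFrame:
    """Transcriptome-wide cell-type-specific association scan.

    Pipeline: compute ``n_pcs`` principal-component covariates from the
    covariate-residualized expression matrix, then fit, per transcript,
    the interaction model jointly with an intercept, the measured
    covariates (every ``phenotype_table`` column except ``phenotype``)
    and the PC covariates; Benjamini-Hochberg q-values are computed
    jointly over all transcript x cell-type tests.  Returns a long-format
    table with columns ``transcript, celltype, estimate, se, t, p, q``
    plus one boolean flag column per requested FDR level.
    """
    y, design, fitted_names, k = _twas_setup(bulk, proportions, phenotype_table, n_pcs)
    delta, se, t, p, _ = _batched_interaction_fit(y, design, k)

    table = pd.DataFrame(
        {
            "transcript": np.repeat(bulk.gene_ids, k),
            "celltype": np.tile(fitted_names, len(bulk.gene_ids)),
            "estimate": delta.ravel(),
            "se": se.ravel(),
            "t": t.ravel(),
            "p": p.ravel(),
        }
    )
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    for level in fdr_levels:
        table[f"sig_{level:g}"] = table["q"] <= level
    return table


def permutation_null(
    bulk: BulkMatrix,
    proportions: ProportionMatrix,
    phenotype_table: pd.DataFrame,
    n_perm: int,
    seed: int = 0,
    n_pcs: int = 6,
) -> pd.DataFrame:
    """Lambda calibration under permuted phenotype labels.

    Runs ``n_perm`` association scans with the phenotype labels randomly
    shuffled (covariates and proportions fixed) and returns the genomic
    inflation factor per permutation and cell type.  The residualization
    and PC covariates do not involve the phenotype, so they are computed
    once.  The result has one row per permutation, one column per cell
    type; summarize with ``.to_numpy().ravel()`` or see
    `AssociationResults.calibrate`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = bulk.sample_ids
    phenotype_table = phenotype_table.loc[samples]
    props = ProportionMatrix(proportions.data.loc[samples])
    d = phenotype_table["phenotype"].to_numpy(dtype=float)
    covars = phenotype_table.drop(columns=["phenotype"])

    y = bulk.values
    blocks = []
    if covars.shape[1]:
        blocks.append(covars.to_numpy(dtype=float))
    if n_pcs > 0:
        resid = residualize(y, covars if covars.shape[1] else None)
        blocks.append(pca_covariates(resid, n_pcs))
    covariate_block = np.column_stack(blocks) if blocks else np.empty((len(samples), 0))

    rng = np.random.default_rng(seed)
    rows = []
    names = None
    for _ in range(n_perm):
        d_perm = d[rng.permutation(d.size)]
        inter, fitted_names = _interaction_design(props, d_perm)
        names = fitted_names
        k = len(fitted_names)
        design = np.column_stack([covariate_block, inter])
        *_, t, _p, _dof = _batched_interaction_fit(y, design, k)
        rows.append([compute_lambda(t[:, j]) for j in range(k)])
    out = pd.DataFrame(rows, columns=names)
    out.index.name = "permutation"
    return out


class CellTypeAssociation:
    """cs-TWAS model binding bulk expression, proportions and phenotypes.

    Parameters
    ----------
    bulk : BulkMatrix
        Transcripts x samples expression (need not share genes with the
        deconvolution panel).
    proportions : ProportionMatrix
        Estimated cell-type proportions for the same samples.
    phenotype_table : pandas.DataFrame
        Indexed by sample ID; the ``phenotype`` column is the trait, all
        other columns are covariates to regress out of expression.
    n_pcs : int
        Number of principal-component covariates appended after the
        measured covariates are removed.
    """

    def __init__(
        self,
        bulk: BulkMatrix,
        proportions: ProportionMatrix,
        phenotype_table: pd.DataFrame,
        n_pcs: int = 6,
    ):
        missing = set(bulk.sample_ids) - set(phenotype_table.index)
        if missing:
            raise ValueError(f"phenotype table missing samples: {sorted(missing)}")
        missing = set(bulk.sample_ids) - set(proportions.sample_ids)
        if missing:
            raise ValueError(f"proportions missing samples: {sorted(missing)}")
        if "phenotype" not in phenotype_table.columns:
            raise ValueError("phenotype table needs a 'phenotype' column")
        self.bulk = bulk
        self.proportions = proportions
        self.phenotype_table = phenotype_table.loc[bulk.sample_ids]
        self.n_pcs = n_pcs

    def fit(self, fdr_levels: tuple[float, ...] = (0.1, 0.25)) -> "AssociationResults":
        table = run_twas(
            self.bulk, self.proportions, self.phenotype_table,
            n_pcs=self.n_pcs, fdr_levels=fdr_levels,
        )
        return AssociationResults(self, table, fdr_levels)


class AssociationResults:
    """Association table plus calibration and summary helpers."""

    def __init__(self, model: CellTypeAssociation, table: pd.DataFrame, fdr_levels):
        self.model = model
        self.table = table
        self.fdr_levels = tuple(fdr_levels)

    @property
    def lambdas(self) -> pd.Series:
        """Observed genomic inflation factor per cell type."""
        return self.table.groupby("celltype", sort=False)["t"].apply(compute_lambda)

    def n_significant(self, level: float) -> int:
        return int((self.table["q"] <= level).sum())

    def calibrate(self, n_perm: int, seed: int = 0) -> pd.DataFrame:
        """Permutation-null lambda table (see `permutation_null`)."""
        return permutation_null(
            self.model.bulk, self.model.proportions, self.model.phenotype_table,
            n_perm=n_perm, seed=seed, n_pcs=self.model.n_pcs,
        )

    def summary(self) -> pd.DataFrame:
        """Per-cell-type summary: lambda and hit counts at each FDR level."""
        out = pd.DataFrame({"lambda": self.lambdas})
        for level in self.fdr_levels:
            col = f"sig_{level:g}"
            out[f"n_{col}"] = self.table.groupby("celltype", sort=False)[col].sum()
        return out
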