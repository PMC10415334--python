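"""Reference panels, bulk matrices and marker selection.

A reference panel is a genes x cell-types matrix of signature expression
values: the design matrix of the deconvolution linear model.  A bulk matrix
is a genes x samples expression matrix whose columns are the response
vectors.  Panels are typically assembled from several single-nucleus
studies: each study's per-cell-type mean profiles are standardized on a
common scale and then averaged, so that no single (e.g. large) study
dominates the panel.

Marker genes — the genes that best discriminate between cell types — are
selected from nucleus-level counts with a two-part hurdle test that combines
a detection-rate (expressed yes/no) chi-square with a two-sample t test on
log-normalized positive counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "BulkMatrix",
    "StudyProfiles",
    "NucleusCounts",
    "read_panel",
    "write_panel",
    "read_bulk",
    "write_bulk",
    "align_genes",
    "build_panel",
    "select_markers",
]


def _check_unique(labels, what: str) -> None:
    seen: dict = {}
    dups = []
    for x in labels:
        if x in seen and x not in dups:
            dups.append(x)
        seen[x] = True
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups))}")


def _check_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite value in {what} at position {tuple(bad)}")


class ReferencePanel:
    """Genes x cell-types matrix of signature expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene ID, columns named by cell type.  Values may be
        on any consistent scale (the estimators never rescale the panel).

    Raises
    ------
    ValueError
        If gene IDs or cell-type names are duplicated, values are missing
        or non-finite, fewer than two cell types are present, or there are
        fewer genes than cell types (an underdetermined design).
    """

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data)
        _check_unique(data.index, "gene IDs")
        _check_unique(data.columns, "cell-type names")
        if data.shape[1] < 2:
            raise ValueError(f"a panel needs at least 2 cell types, got {data.shape[1]}")
        if data.shape[0] < data.shape[1]:
            raise ValueError(
                f"underdetermined panel: {data.shape[0]} genes < {data.shape[1]} cell types"
            )
        values = data.to_numpy(dtype=float)
        _check_finite(values, "panel")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
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
        g, k = self.shape
        return f"ReferencePanel({g} genes x {k} cell types)"


class BulkMatrix:
    """Genes x samples bulk expression matrix sharing gene IDs with a panel."""

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data)
        _check_unique(data.index, "gene IDs")
        _check_unique(data.columns, "sample IDs")
        values = data.to_numpy(dtype=float)
        _check_finite(values, "bulk matrix")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, n = self.shape
        return f"BulkMatrix({g} genes x {n} samples)"


@dataclass
class StudyProfiles:
    """Per-study, per-cell-type mean expression profiles.

    ``mean_expr`` is a genes x cell-types DataFrame of per-cell-type mean
    expression for one study, on whatever scale the study uses; `build_panel`
    standardizes it before averaging across studies.
    """

    study_id: str
    mean_expr: pd.DataFrame

    def __post_init__(self):
        self.mean_expr = pd.DataFrame(self.mean_expr).astype(float)
        _check_unique(self.mean_expr.index, f"gene IDs in study {self.study_id!r}")
        _check_finite(self.mean_expr.to_numpy(), f"study {self.study_id!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_expr.index)

    @property
    def celltype_names(self) -> list[str]:
        return list(self.mean_expr.columns)


@dataclass
class NucleusCounts:
    """Nucleus-level UMI counts with per-nucleus cell-type labels."""

    counts: pd.DataFrame  # genes x nuclei, non-negative integers
    celltype_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "gene IDs")
        _check_unique(self.counts.columns, "nucleus IDs")
        vals = self.counts.to_numpy()
        _check_finite(np.asarray(vals, dtype=float), "counts")
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")
        self.celltype_labels = list(self.celltype_labels)
        if len(self.celltype_labels) != self.counts.shape[1]:
            raise ValueError(
                f"{len(self.celltype_labels)} labels for {self.counts.shape[1]} nuclei"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def nucleus_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# I/O: tab-separated text, header row of column names, first column gene_id
# ---------------------------------------------------------------------------

def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_filter=False)
    df.index = df.index.astype(str)
    # reject non-numeric cells with an informative location
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, v in enumerate(df[col]):
            try:
                out[i, j] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {v!r} at gene {df.index[i]!r}, column {col!r}"
                ) from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_panel(path) -> ReferencePanel:
    """Read a reference panel from a tab-separated text file.

    The first row is a header of cell-type names, the first column holds the
    gene IDs; remaining cells must parse as numbers.
    """
    return ReferencePanel(_read_matrix(path))


def write_panel(panel: ReferencePanel, path) -> None:
    """Write a panel as TSV with a ``gene_id`` first column."""
    panel.data.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")


def read_bulk(path) -> BulkMatrix:
    """Read a genes x samples bulk matrix from TSV (same layout as panels)."""
    return BulkMatrix(_read_matrix(path))


def write_bulk(bulk: BulkMatrix, path) -> None:
    bulk.data.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")


def align_genes(panel: ReferencePanel, bulk: BulkMatrix) -> tuple[ReferencePanel, BulkMatrix]:
    """Restrict panel and bulk to their shared genes, in identical row order.

    Row order follows the panel's ordering of the intersection.

    Raises
    ------
    ValueError
        If the gene sets are disjoint, or the intersection has fewer genes
        than the panel has cell types (underdetermined fit).
    """
    shared = [g for g in panel.gene_ids if g in set(bulk.gene_ids)]
    if not shared:
        raise ValueError("panel and bulk share no genes")
    k = len(panel.celltype_names)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared genes for {k} cell types: underdetermined"
        )
    logger.info("align_genes: %d shared genes", len(shared))
    return ReferencePanel(panel.data.loc[shared]), BulkMatrix(bulk.data.loc[shared])


def build_panel(profiles: list[StudyProfiles]) -> ReferencePanel:
    """Assemble a reference panel by averaging standardized study profiles.

    Each study's profile matrix is standardized gene-wise — every gene's
    values are centered and scaled to unit variance across that study's
    cell-type means (zero-variance genes are set to all-zeros for that
    study) — and the standardized matrices are averaged, unweighted, over
    the genes present in every study.  Cell-type columns are canonicalized
    alphabetically.

    Raises
    ------
    ValueError
        If no studies are given or the studies' cell-type sets differ.
    """
    if not profiles:
        raise ValueError("at least one study profile is required")
    ct0 = set(profiles[0].celltype_names)
    for p in profiles[1:]:
        if set(p.celltype_names) != ct0:
            diff = sorted(ct0.symmetric_difference(p.celltype_names))
            raise ValueError(
                f"cell-type sets differ between studies "
                f"{profiles[0].study_id!r} and {p.study_id!r}: {', '.join(diff)}"
            )
    celltypes = sorted(ct0)
    shared = set(profiles[0].gene_ids)
    for p in profiles[1:]:
        shared &= set(p.gene_ids)
    if len(shared) < len(celltypes):
        raise ValueError(
            f"only {len(shared)} genes shared by all studies for {len(celltypes)} cell types"
        )
    # preserve first study's gene order for determinism
    genes = [g for g in profiles[0].gene_ids if g in shared]
    acc = np.zeros((len(genes), len(celltypes)))
    for p in profiles:
        m = p.mean_expr.loc[genes, celltypes].to_numpy()
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, ddof=1, keepdims=True)
        z = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        acc += z
    acc /= len(profiles)
    return ReferencePanel(pd.DataFrame(acc, index=genes, columns=celltypes))


# ---------------------------------------------------------------------------
# Marker selection: two-part hurdle test on nucleus-level counts
# ---------------------------------------------------------------------------

def _lognorm(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log(1 + count / nucleus_total * scale), the standard library-size
    normalization for droplet counts."""
    totals = counts.sum(axis=0, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * scale)


def hurdle_test(x_in: np.ndarray, x_out: np.ndarray) -> tuple[float, float]:
    """Two-part hurdle statistic for one gene, one cell type vs the rest.

    The discrete part is the chi-square (with continuity correction) of the
    2x2 table expressed-yes/no x in-type/out-of-type.  The continuous part
    is the squared two-sample t statistic on log-normalized positive values
    (0 if either side has fewer than 2 positive nuclei).  Their sum is
    referred to a chi-square distribution with 2 df.

    Parameters are the log-normalized expression vectors for the in-type
    and out-of-type nuclei.  Returns ``(statistic, p_value)``.
    """
    pos_in = x_in[x_in > 0]
    pos_out = x_out[x_out > 0]
    table = np.array(
        [
            [pos_in.size, x_in.size - pos_in.size],
            [pos_out.size, x_out.size - pos_out.size],
        ]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2_part = 0.0  # detection rate identical (all on or all off)
    else:
        chi2_part = stats.chi2_contingency(table, correction=True)[0]
    if pos_in.size >= 2 and pos_out.size >= 2:
        t = stats.ttest_ind(pos_in, pos_out, equal_var=True).statistic
        t_part = 0.0 if not np.isfinite(t) else float(t) ** 2
    else:
        t_part = 0.0
    stat = float(chi2_part) + t_part
    return stat, float(stats.chi2.sf(stat, df=2))


def select_markers(
    counts: NucleusCounts,
    top_n_per_type: int,
    alpha: float = 0.05,
) -> list[str]:
    """Select discriminating marker genes from nucleus-level counts.

    For every gene and cell type a one-vs-rest hurdle test is computed on
    log-normalized counts (see `hurdle_test`).  Within each cell type genes
    are ranked by p-value, ties broken by descending log-fold-change, and
    the union over cell types of the ``top_n_per_type`` best genes is
    returned — restricted to genes whose Benjamini-Hochberg q-value (within
    that cell type's family of tests) is at most ``alpha``.

    Returns the selected gene IDs sorted alphabetically.
    """
    labels = np.asarray(counts.celltype_labels)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("marker selection needs at least 2 cell types")
    for t in types:
        if (labels == t).sum() < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 nuclei")
    x = _lognorm(counts.counts.to_numpy().astype(float))
    genes = np.asarray(counts.gene_ids)
    selected: set[str] = set()
    for t in types:
        mask = labels == t
        pvals = np.empty(len(genes))
        lfc = np.empty(len(genes))
        for gi in range(len(genes)):
            _, pvals[gi] = hurdle_test(x[gi, mask], x[gi, ~mask])
            lfc[gi] = x[gi, mask].mean() - x[gi, ~mask].mean()
        qvals = multipletests(pvals, method="fdr_bh")[1]
        order = np.lexsort((-lfc, pvals))
        picked = [genes[i] for i in order[:top_n_per_type] if qvals[i] <= alpha]
        selected.update(picked)
    return sorted(selected)
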