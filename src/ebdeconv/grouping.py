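"""Grouping of similar cell types by PCA with varimax rotation.

Transcriptionally similar cell types (e.g. two oligodendrocyte clusters)
carry similar association signal; merging their proportions before the
association stage reduces the number of tests and can improve power.  The
grouping treats the panel's cell types as variables and its genes as
observations: components with eigenvalue above one (Kaiser criterion) are
varimax-rotated, and all cell types loading above a threshold (default
loading > 0.5, after fixing each component's sign so its dominant loading
is positive) on the same rotated component are merged into one group.
The signed rule matters: two unrelated cell types can share a retained
component with loadings of opposite sign, and only positively co-loading
(transcriptionally similar) types should merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ProportionMatrix
from .panel import ReferencePanel

logger = logging.getLogger(__name__)

__all__ = ["GroupingResult", "varimax", "group_celltypes", "merge_proportions"]


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Orthogonal rotation maximizing the variance of squared loadings
    (Kaiser's criterion), with row (communality) normalization by default —
    the same convention as R's ``stats::varimax``.  Returns the rotated
    loadings and the rotation matrix.
    """
    x = np.asarray(loadings, dtype=float).copy()
    p, k = x.shape
    if k < 2:
        return x, np.eye(k)
    if normalize:
        h = np.sqrt((x**2).sum(axis=1))
        h[h == 0] = 1.0
        x = x / h[:, None]
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        d_old = d
        lam = x @ rot
        u, s, vt = np.linalg.svd(
            x.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
    out = x @ rot
    if normalize:
        out = out * h[:, None]
    return out, rot


@dataclass
class GroupingResult:
    """Rotated loadings and the cell-type -> group assignment they imply."""

    loadings: pd.DataFrame  # cell types x retained components
    groups: dict[str, str]  # cell type -> group label
    retained_components: int

    def group_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for ct, g in self.groups.items():
            members.setdefault(g, []).append(ct)
        return members

    def to_frame(self) -> pd.DataFrame:
        top = self.loadings.abs().max(axis=1) if self.retained_components else pd.Series(
            np.nan, index=list(self.groups)
        )
        return pd.DataFrame(
            {"group": [self.groups[ct] for ct in self.loadings.index],
             "top_loading": [float(top[ct]) for ct in self.loadings.index]},
            index=pd.Index(self.loadings.index, name="celltype"),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def group_celltypes(
    panel: ReferencePanel, loading_threshold: float = 0.5
) -> GroupingResult:
    """Group cell types whose varimax-rotated loadings co-locate.

    PCA is run on the column-standardized panel (cell types as variables,
    genes as observations); components with eigenvalue > 1 are retained
    and varimax-rotated, each component's sign fixed so its
    largest-magnitude loading is positive.  Cell types with
    ``loading > loading_threshold`` on the same rotated component form one
    group; a cell type exceeding the threshold on several components is
    assigned to the component with its largest loading (with a warning);
    cell types exceeding it nowhere stay singletons.
    """
    x = panel.values
    g, k = x.shape
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a constant panel column cannot be standardized")
    z = (x - mu) / sd
    corr = z.T @ z / (g - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1.0  # Kaiser criterion
    r = int(keep.sum())
    names = panel.celltype_names
    if r == 0:
        loadings = pd.DataFrame(np.empty((k, 0)), index=names)
        return GroupingResult(loadings, {ct: ct for ct in names}, 0)
    load = eigvec[:, :r] * np.sqrt(eigval[:r])
    rotated, _ = varimax(load)
    rotated = _fix_signs(rotated)
    loadings = pd.DataFrame(rotated, index=names, columns=[f"RC{j + 1}" for j in range(r)])

    assigned: dict[str, int | None] = {}
    for i, ct in enumerate(names):
        above = np.flatnonzero(rotated[i] > loading_threshold)
        if above.size == 0:
            assigned[ct] = None
        elif above.size == 1:
            assigned[ct] = int(above[0])
        else:
            best = int(above[np.argmax(rotated[i, above])])
            logger.warning(
                "cell type %r loads > %.2f on %d components; assigned to RC%d",
                ct, loading_threshold, above.size, best + 1,
            )
            assigned[ct] = best
    groups: dict[str, str] = {}
    for j in range(r):
        members = [ct for ct in names if assigned[ct] == j]
        if members:
            label = "+".join(members)
            for ct in members:
                groups[ct] = label
    for ct in names:
        if assigned[ct] is None:
            groups[ct] = ct
    return GroupingResult(loadings, groups, r)


def merge_proportions(
    proportions: ProportionMatrix, grouping: GroupingResult
) -> ProportionMatrix:
    """Sum member proportions within each group (proportions are mass).

    Row sums are preserved exactly; group columns are ordered by the first
    appearance of a member in the input.
    """
    unknown = [ct for ct in proportions.celltype_names if ct not in grouping.groups]
    if unknown:
        raise ValueError(f"cell types missing from grouping: {', '.join(unknown)}")
    order: list[str] = []
    for ct in proportions.celltype_names:
        label = grouping.groups[ct]
        if label not in order:
            order.append(label)
    merged = pd.DataFrame(0.0, index=proportions.data.index, columns=order)
    for ct in proportions.celltype_names:
        merged[grouping.groups[ct]] += proportions.data[ct]
    return ProportionMatrix(merged)
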