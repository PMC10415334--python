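"""Scoring of estimated against true cell-type proportions.

Four metrics per cell type, computed over samples: bias (signed mean
error), RMSE, the number of proportions estimated at exactly zero, and the
Pearson correlation between true and estimated values.  An unweighted
"Average" row over cell types summarizes each column; correlations that
are undefined (a constant column) are excluded from the average with a
logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import ProportionMatrix

logger = logging.getLogger(__name__)

__all__ = ["evaluate_estimates", "score_external", "AVERAGE_ROW"]

AVERAGE_ROW = "Average"


def evaluate_estimates(true: ProportionMatrix, est: ProportionMatrix) -> pd.DataFrame:
    """Score an estimated proportion matrix against the truth.

    Returns a DataFrame indexed by cell type with columns ``bias``,
    ``rmse``, ``zero`` and ``cor``, plus a final ``Average`` row holding
    the unweighted column means (zero counts averaged as real numbers).
    ``zero`` counts exact zeros only, matching the truncation semantics of
    the EB estimator.
    """
    if set(true.sample_ids) != set(est.sample_ids):
        raise ValueError("sample sets differ between true and estimated proportions")
    if set(true.celltype_names) != set(est.celltype_names):
        diff = sorted(set(true.celltype_names) ^ set(est.celltype_names))
        raise ValueError(f"cell-type sets differ: {', '.join(diff)}")
    t = true.data
    e = est.data.loc[t.index, t.columns]
    rows = {}
    for ct in t.columns:
        err = e[ct].to_numpy() - t[ct].to_numpy()
        cor = np.nan
        if t[ct].std() > 0 and e[ct].std() > 0:
            cor = float(np.corrcoef(t[ct], e[ct])[0, 1])
        else:
            logger.warning("correlation undefined for constant cell type %r", ct)
        rows[ct] = {
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "zero": int(np.sum(e[ct].to_numpy() == 0.0)),
            "cor": cor,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    avg = {
        "bias": table["bias"].mean(),
        "rmse": table["rmse"].mean(),
        "zero": table["zero"].mean(),
        "cor": table["cor"].mean(skipna=True),  # undefined correlations excluded
    }
    table.loc[AVERAGE_ROW] = avg
    table.index.name = "celltype"
    return table


def score_external(true_path, est_path) -> pd.DataFrame:
    """Score an external estimator's output file against a truth file.

    Both files are samples x cell-types TSV with a header row and sample
    IDs in the first column; labels are aligned order-insensitively, so
    any deconvolution tool's output can be dropped in.
    """
    true_df = pd.read_csv(true_path, sep="\t", index_col=0)
    est_df = pd.read_csv(est_path, sep="\t", index_col=0)
    missing_ct = sorted(set(true_df.columns) ^ set(est_df.columns))
    if missing_ct:
        raise ValueError(f"cell-type labels differ between files: {', '.join(missing_ct)}")
    missing_s = sorted(set(true_df.index) ^ set(est_df.index))
    if missing_s:
        raise ValueError(f"sample labels differ between files: {', '.join(map(str, missing_s))}")
    est_df = est_df.loc[true_df.index, true_df.columns]
    return evaluate_estimates(ProportionMatrix(true_df), ProportionMatrix(est_df))
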