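"""Per-cell signature scoring, pseudobulk aggregation and condition tests.

Cells are depth-normalized (counts-per-10k, log1p), genes are z-scored
across the pooled cells of *all* conditions, and each cell's signature
score is the sum of its z-scores over the signature genes — the same
sum-z machinery used for bulk cohorts.  Pooling conditions before
z-scoring is essential: a per-condition reference would absorb exactly
the treatment shift the comparison is meant to measure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats as sps

from .signatures import GeneSignature
from .scoring import _match_genes

__all__ = [
    "normalize_cells",
    "cell_signature_score",
    "pseudobulk",
    "compare_condition_scores",
]

logger = logging.getLogger(__name__)


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def normalize_cells(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Depth-normalize raw counts: value = log(1 + scale * count / total).

    Returns a new AnnData with normalized values in ``X`` and the raw
    counts kept in ``layers["counts"]``.  Cells with zero total counts are
    rejected by ID — they carry no expression information.
    """
    counts = _dense(adata.X)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"cells with zero total counts: {list(adata.obs_names[zero])}"
        )
    norm = np.log1p(scale * counts / totals[:, None])
    out = AnnData(norm, obs=adata.obs.copy(), var=adata.var.copy())
    out.layers["counts"] = counts
    return out


def cell_signature_score(
    adata: AnnData, signature: GeneSignature, condition_key: str = "condition"
) -> pd.DataFrame:
    """Sum-z signature score per cell on a normalized matrix.

    Genes are z-scored across all cells pooled (ddof=1; constant genes map
    to zero), and the score is the per-cell sum over signature genes found
    in the matrix.  Missing signature genes are logged.  Returns a
    DataFrame with columns cell, signature, score and condition.
    """
    var_index = pd.Index(adata.var_names)
    present, missing = _match_genes(var_index, signature)
    if missing:
        logger.warning(
            "signature %s: %d/%d genes missing from cell matrix: %s",
            signature.name, len(missing), len(signature), ", ".join(missing),
        )
    if not present:
        raise KeyError(f"no gene of signature {signature.name!r} in cell matrix")
    x = _dense(adata[:, present].X)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    # identical values can yield a tiny nonzero sd from accumulated rounding
    constant = np.ptp(x, axis=0) == 0 if x.shape[0] > 1 else np.ones(x.shape[1], bool)
    if constant.any():
        logger.warning("%d constant signature gene(s) mapped to z=0", int(constant.sum()))
    z = (x - mean) / np.where(constant, 1.0, sd)
    z[:, constant] = 0.0
    scores = z.sum(axis=1)
    out = pd.DataFrame(
        {
            "cell": adata.obs_names,
            "signature": signature.name,
            "score": scores,
        }
    )
    if condition_key in adata.obs:
        out["condition"] = adata.obs[condition_key].to_numpy()
    return out


def pseudobulk(adata: AnnData, condition_key: str = "condition") -> pd.DataFrame:
    """Sum raw counts over the cells of each condition.

    Returns a genes x conditions DataFrame whose grand total equals the
    grand total of the input counts exactly.
    """
    if condition_key not in adata.obs:
        raise KeyError(f"cell metadata lacks column {condition_key!r}")
    counts = adata.layers["counts"] if "counts" in adata.layers else _dense(adata.X)
    counts = _dense(counts)
    cond = pd.Series(adata.obs[condition_key].to_numpy(), dtype="object")
    if cond.isna().any():
        raise ValueError("every cell must carry a condition label")
    cols = {}
    for label in cond.unique():
        cols[label] = counts[(cond == label).to_numpy()].sum(axis=0)
    return pd.DataFrame(cols, index=adata.var_names)


def compare_condition_scores(
    scores: pd.DataFrame,
    signature_name: str,
    cond_a: str,
    cond_b: str,
) -> dict:
    """Welch two-sample t-test of per-cell scores between two conditions.

    Direction is reported as mean(cond_b) - mean(cond_a), so a negative
    shift means the score is lower in ``cond_b`` (e.g. the treated arm).
    """
    sub = scores.loc[scores["signature"] == signature_name]
    a = sub.loc[sub["condition"] == cond_a, "score"].to_numpy(dtype=float)
    b = sub.loc[sub["condition"] == cond_b, "score"].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least 2 cells")
    t, p = sps.ttest_ind(b, a, equal_var=False)
    return {
        "signature": signature_name,
        "mean_difference": float(b.mean() - a.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
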