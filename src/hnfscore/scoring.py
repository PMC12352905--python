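"""Sum-z signature scoring of bulk expression matrices.

The scoring model: expression is quantified as transcripts per million
(TPM), log2-transformed with a pseudocount, each gene is z-scored across
the samples of the cohort (the cohort itself is the reference population),
and a sample's signature score is the sum of its z-scores over the
signature genes.  Samples are stratified at fixed score thresholds:
score >= 12 is High, score <= 0 is Low, anything between is Intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "ExpressionMatrix",
    "log2_transform",
    "gene_zscores",
    "sum_z_score",
    "stratify_hnf",
    "score_cohort",
    "HIGH_THRESHOLD",
    "LOW_THRESHOLD",
]

logger = logging.getLogger(__name__)

HIGH_THRESHOLD = 12.0
LOW_THRESHOLD = 0.0


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbols, columns are unique
        sample IDs.
    scale
        ``"tpm"`` for linear TPM values, ``"log2tpm"`` for
        log2(TPM + pseudocount).
    """

    values: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2tpm"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        idx = self.values.index.astype(str).str.strip()
        dup = idx[idx.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene symbols: {sorted(set(dup))}")
        cols = self.values.columns.astype(str)
        if cols.duplicated().any():
            raise ValueError("duplicate sample IDs")
        self.values = self.values.copy()
        self.values.index = idx
        self.values.columns = cols
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale == "tpm":
            vals = self.values.to_numpy()
            if (vals < 0).any():
                g, s = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative TPM value at gene {self.values.index[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount) transform of a linear-scale matrix."""
    if matrix.scale != "tpm":
        raise ValueError("matrix is already log-transformed")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(np.log2(matrix.values + pseudocount), scale="log2tpm")


def gene_zscores(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, ddof=1).

    Genes with zero variance across the cohort are mapped to an all-zero
    row (with a warning) rather than NaN.  Requires at least two samples.
    """
    if matrix.scale != "log2tpm":
        raise ValueError("z-scores are computed on log2-transformed values")
    if matrix.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    vals = matrix.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    # identical values can yield a tiny nonzero sd from accumulated rounding
    constant = (vals.max(axis=1) - vals.min(axis=1)) == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s) mapped to z=0: %s",
            int(constant.sum()),
            ", ".join(vals.index[constant][:10]),
        )
    z = vals.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    return z


def _match_genes(index: pd.Index, signature: GeneSignature) -> tuple[list[str], list[str]]:
    """Case-insensitive signature-gene lookup; returns (matrix rows, missing)."""
    lookup = {g.upper(): g for g in index}
    present, missing = [], []
    for gene in signature:
        row = lookup.get(gene.strip().upper())
        (present if row is not None else missing).append(row if row is not None else gene)
    return present, missing


def sum_z_score(
    zmatrix: pd.DataFrame,
    signature: GeneSignature,
    missing_policy: str = "drop_warn",
) -> pd.DataFrame:
    """Per-sample summed z-score over the signature genes.

    Returns a DataFrame indexed by sample with columns ``signature``,
    ``score``, ``n_genes_used`` and ``missing_genes``.  Genes absent from
    the matrix are either an error (``missing_policy="error"``) or dropped
    with a warning and recorded (``"drop_warn"``, the default — real
    matrices lose symbols to annotation drift).
    """
    if missing_policy not in ("error", "drop_warn"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    present, missing = _match_genes(zmatrix.index, signature)
    if missing:
        if missing_policy == "error":
            raise KeyError(
                f"signature {signature.name!r} genes absent from matrix: {missing}"
            )
        logger.warning(
            "signature %s: %d/%d genes missing from matrix: %s",
            signature.name, len(missing), len(signature), ", ".join(missing),
        )
    if not present:
        raise KeyError(f"no gene of signature {signature.name!r} found in matrix")
    scores = zmatrix.loc[present].sum(axis=0)
    return pd.DataFrame(
        {
            "signature": signature.name,
            "score": scores,
            "n_genes_used": len(present),
            "missing_genes": ",".join(missing),
        },
        index=scores.index.rename("sample"),
    )


def stratify_hnf(
    scores: pd.DataFrame,
    high_threshold: float = HIGH_THRESHOLD,
    low_threshold: float = LOW_THRESHOLD,
    two_level: bool = False,
) -> pd.DataFrame:
    """Assign High / Intermediate / Low strata from sum-z scores.

    score >= ``high_threshold`` is High, score <= ``low_threshold`` is Low,
    anything between is Intermediate.  With ``two_level=True`` every
    non-High sample is labelled Low (the split used for the 25-patient
    enzalutamide-response cohort, where no sample fell in between).
    """
    if not low_threshold < high_threshold:
        raise ValueError("low_threshold must be below high_threshold")
    s = pd.to_numeric(scores["score"], errors="raise")
    out = scores.copy()
    if two_level:
        out["stratum"] = np.where(s >= high_threshold, "High", "Low")
    else:
        out["stratum"] = np.select(
            [s >= high_threshold, s <= low_threshold], ["High", "Low"], "Intermediate"
        )
    return out


def score_cohort(
    matrix: ExpressionMatrix,
    signatures: list[GeneSignature],
    pseudocount: float = 1.0,
    missing_policy: str = "drop_warn",
    high_threshold: float = HIGH_THRESHOLD,
    low_threshold: float = LOW_THRESHOLD,
    two_level: bool = False,
) -> pd.DataFrame:
    """Convenience pipeline: transform (if needed), z-score, score, stratify.

    Stratification is applied to the signature named ``"HNF"`` only; other
    signatures get an empty stratum.
    """
    if matrix.scale == "tpm":
        matrix = log2_transform(matrix, pseudocount)
    z = gene_zscores(matrix)
    tables = []
    for sig in signatures:
        t = sum_z_score(z, sig, missing_policy=missing_policy)
        if sig.name == "HNF":
            t = stratify_hnf(t, high_threshold, low_threshold, two_level=two_level)
        else:
            t["stratum"] = ""
        tables.append(t)
    return pd.concat(tables).reset_index().set_index(["sample", "signature"]).reset_index()
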