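"""File I/O and the end-to-end scoring/association pipeline.

Readers accept the plain-text formats the analysis consumes: delimited
expression matrices (genes x samples, or transposed with a flag), GMT
gene sets, sample metadata CSVs with response and survival columns, MTX
triplets or dense TSVs for single-cell counts, and CSV tables for IHC
counts and tumor growth.  ``run_pipeline`` ties the bulk-cohort stages
together — score, stratify, Fisher association, Kaplan-Meier/log-rank —
and writes a JSON manifest capturing everything needed for an identical
rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from . import __version__
from .scoring import (
    ExpressionMatrix,
    HIGH_THRESHOLD,
    LOW_THRESHOLD,
    score_cohort,
)
from .signatures import GeneSignature, ar_signature, hnf_signature, read_gmt
from .stats import fisher_exact_2x2, km_estimator, logrank_test, median_survival

__all__ = [
    "read_expression",
    "read_metadata",
    "read_cell_matrix",
    "read_stain_counts",
    "read_growth",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

RESPONSE_LEVELS = ("nonresponder", "responder")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, orientation: str = "genes_by_samples",
                    scale: str = "tpm") -> ExpressionMatrix:
    """Read a delimited expression matrix (first column = gene symbols).

    ``orientation="samples_by_genes"`` transposes after reading.  The
    delimiter is inferred from the extension (.csv comma, otherwise tab).
    Duplicate labels, ragged rows and non-numeric cells are rejected with
    context.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    bad = df.columns[df.isna().any(axis=0)]
    if len(bad):
        raise ValueError(f"{path}: missing/non-numeric cells in columns {list(bad)}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
    return ExpressionMatrix(df, scale=scale)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata CSV (sample, response, survival columns)."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path))
    if "sample" not in meta.columns:
        raise ValueError(f"{path}: metadata requires a 'sample' column")
    if meta["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in metadata")
    if "response" in meta.columns:
        bad = set(meta["response"].dropna()) - set(RESPONSE_LEVELS)
        if bad:
            raise ValueError(f"{path}: unknown response levels {sorted(bad)}")
    return meta


def read_cell_matrix(
    path: str | Path,
    meta_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> AnnData:
    """Read single-cell counts from an MTX triplet or a dense TSV.

    For MTX input the matrix is genes x cells (the conventional triplet
    layout) with one gene symbol per line in ``genes_path`` and one
    barcode per line in ``barcodes_path``.  Dense TSV input is cells x
    genes with barcodes in the first column.  ``meta_path`` is a CSV with
    columns cell, condition and optionally cluster.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise ValueError("MTX input requires genes and barcodes files")
        m = scipy.io.mmread(path)
        counts = (m.tocsr().T if sp.issparse(m) else np.asarray(m).T)
        genes = [ln.strip().split("\t")[0] for ln in open(genes_path) if ln.strip()]
        cells = [ln.strip() for ln in open(barcodes_path) if ln.strip()]
        counts = np.asarray(counts.todense()) if sp.issparse(counts) else counts
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        counts = df.to_numpy()
        genes = list(df.columns)
        cells = list(df.index.astype(str))
    if counts.shape != (len(cells), len(genes)):
        raise ValueError(
            f"count matrix shape {counts.shape} does not match "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    obs = pd.DataFrame(index=pd.Index(cells, name="cell"))
    if meta_path is not None:
        meta = pd.read_csv(meta_path).set_index("cell")
        missing = obs.index.difference(meta.index)
        if len(missing):
            raise ValueError(f"cells missing from metadata: {list(missing[:5])}")
        obs = meta.reindex(obs.index)
    adata = AnnData(counts, obs=obs, var=pd.DataFrame(index=genes))
    return adata


def read_stain_counts(path: str | Path) -> pd.DataFrame:
    """Read an IHC stain-intensity count CSV."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    required = {"region", "sample", "n_negative", "n_weak", "n_moderate", "n_strong"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_growth(path: str | Path) -> pd.DataFrame:
    """Read a tumor-growth measurement CSV (animal, arm, day, volume_mm3)."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    missing = {"animal", "arm", "day", "volume_mm3"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["volume_mm3"] <= 0).any():
        raise ValueError(f"{path}: tumor volumes must be positive")
    order_ok = df.groupby("animal")["day"].apply(lambda s: s.is_monotonic_increasing and s.is_unique)
    if not order_ok.all():
        bad = order_ok.index[~order_ok][0]
        raise ValueError(f"{path}: days not strictly increasing for animal {bad!r}")
    return df


@dataclass
class RunConfig:
    """Configuration of the bulk score -> stratify -> associate pipeline."""

    expression: str
    metadata: str | None = None
    outdir: str = "results"
    gmt: list[str] = field(default_factory=list)
    orientation: str = "genes_by_samples"
    scale: str = "tpm"
    pseudocount: float = 1.0
    missing_policy: str = "drop_warn"
    high_threshold: float = HIGH_THRESHOLD
    low_threshold: float = LOW_THRESHOLD
    two_level: bool = False
    seed: int = 0


def _survival_block(meta: pd.DataFrame, scores: pd.DataFrame,
                    time_col: str, event_col: str) -> dict | None:
    if time_col not in meta.columns or event_col not in meta.columns:
        return None
    merged = meta.merge(
        scores.loc[scores["signature"] == "HNF", ["sample", "stratum"]], on="sample"
    ).dropna(subset=[time_col, event_col])
    groups = merged["stratum"]
    if groups.nunique() < 2:
        return None
    stat, p = logrank_test(merged[time_col], merged[event_col], groups)
    medians = {}
    for label, sub in merged.groupby("stratum"):
        curve = km_estimator(sub[time_col], sub[event_col])
        medians[label] = median_survival(curve)
    return {
        "endpoint": time_col,
        "logrank_chi2": stat,
        "logrank_p": p,
        "group_sizes": merged["stratum"].value_counts().to_dict(),
        "median_survival": medians,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Score a cohort, stratify, and associate strata with outcomes.

    Writes ``scores.tsv``, ``association.json`` and ``manifest.json``
    into ``config.outdir`` and returns the result bundle as a dict.
    Signature sources: any GMT files in ``config.gmt`` plus the built-in
    HNF and combined AR panels when no GMT is given.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = read_expression(config.expression, config.orientation, config.scale)
    if config.gmt:
        signatures: list[GeneSignature] = []
        for g in config.gmt:
            signatures.extend(read_gmt(g))
    else:
        signatures = [hnf_signature(), ar_signature()]
    scores = score_cohort(
        matrix,
        signatures,
        pseudocount=config.pseudocount,
        missing_policy=config.missing_policy,
        high_threshold=config.high_threshold,
        low_threshold=config.low_threshold,
        two_level=config.two_level,
    )
    scores_path = outdir / "scores.tsv"
    scores.to_csv(scores_path, sep="\t", index=False)

    association: dict = {}
    if config.metadata is not None:
        meta = read_metadata(config.metadata)
        hnf_scores = scores.loc[scores["signature"] == "HNF"]
        merged = meta.merge(hnf_scores[["sample", "stratum"]], on="sample")
        if "response" in merged.columns:
            high = merged["stratum"] == "High"
            nonresp = merged["response"] == "nonresponder"
            a = int((high & nonresp).sum())
            b = int((high & ~nonresp).sum())
            c = int((~high & nonresp).sum())
            d = int((~high & ~nonresp).sum())
            association["response"] = {
                "table": {"high_nonresponder": a, "high_responder": b,
                          "rest_nonresponder": c, "rest_responder": d},
                "fisher_p": fisher_exact_2x2(a, b, c, d),
            }
        for time_col, event_col in (("tot_time", "tot_event"), ("os_time", "os_event")):
            block = _survival_block(meta, scores, time_col, event_col)
            if block is not None:
                association[time_col] = block
        with open(outdir / "association.json", "w") as fh:
            json.dump(association, fh, indent=2, sort_keys=True)

    manifest = {
        "tool": "hnfscore",
        "version": __version__,
        "config": asdict(config),
        "signatures": {s.name: list(s.genes) for s in signatures},
        "n_genes": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"scores": scores, "association": association, "manifest": manifest}
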