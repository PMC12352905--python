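"""Immunohistochemistry quantification: H-scores and positive-cell fractions.

The H-score summarizes nuclear DAB staining of a region as a weighted sum
of the *percentages* of cells staining weak (x1), moderate (x2) and strong
(x3), giving a bounded score in [0, 300].  Working on percentages rather
than raw nuclei counts makes regions of different cellularity comparable
and reproduces the conventional 0-300 range used in the downstream
figures.  Intensity binning (what counts as weak/moderate/strong) is an
upstream image-analysis choice; this module consumes pre-binned counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["h_score", "mean_h_score", "positive_fraction"]

INTENSITY_COLUMNS = ("n_negative", "n_weak", "n_moderate", "n_strong")
_WEIGHTS = np.array([0.0, 1.0, 2.0, 3.0])


def h_score(n_negative: int, n_weak: int, n_moderate: int, n_strong: int) -> float:
    """H-score of one region: 100 * (1*%weak + 2*%moderate + 3*%strong).

    Percentages are fractions of all counted nuclei (negative included),
    so 0 <= H <= 300 with 300 attained only when every nucleus stains
    strongly.
    """
    counts = np.array([n_negative, n_weak, n_moderate, n_strong], dtype=float)
    if (counts < 0).any():
        raise ValueError("stain counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("region has no counted nuclei")
    return float(100.0 * (_WEIGHTS * counts).sum() / total)


def mean_h_score(regions: pd.DataFrame, sample: str) -> dict:
    """Mean +/- SEM of region H-scores for one sample.

    ``regions`` needs columns region, sample and the four intensity counts.
    SEM uses ddof=1 and is NaN with a single region.
    """
    sub = regions.loc[regions["sample"] == sample]
    if sub.empty:
        raise ValueError(f"no stained regions for sample {sample!r}")
    scores = np.array(
        [h_score(*row) for row in sub[list(INTENSITY_COLUMNS)].to_numpy()]
    )
    sem = float(np.std(scores, ddof=1) / np.sqrt(scores.size)) if scores.size > 1 else float("nan")
    return {
        "sample": sample,
        "n_regions": int(scores.size),
        "mean_h_score": float(scores.mean()),
        "sem": sem,
    }


def positive_fraction(n_positive: int, n_total: int) -> float:
    """Fraction of positively stained cells (e.g. Ki67 or p21) in [0, 1]."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    return n_positive / n_total
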