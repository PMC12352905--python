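"""Outcome-association statistics.

Self-contained implementations of the exact and survival statistics the
analysis relies on: two-sided Fisher's exact test on 2x2 tables by full
hypergeometric enumeration, the Kaplan-Meier product-limit estimator,
median survival read-off, and the k-group log-rank (Mantel-Cox) test.
Also the xenograft tumor-volume formula V = (D*d*h)/6 and growth
fold-change summaries.

Fisher and the survival estimators are implemented here (not delegated)
because their conventions — which hypergeometric outcomes count as "as
extreme", how censored subjects at an event time are handled — are part of
the analysis contract; independent library implementations serve as
cross-checks in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact_2x2",
    "KMCurve",
    "km_estimator",
    "median_survival",
    "logrank_test",
    "pearson_correlation",
    "tumor_volume",
    "growth_fold_change",
    "arm_fold_changes",
    "arm_volume_ratio",
]

logger = logging.getLogger(__name__)

# Relative guard for float ties when comparing hypergeometric pmf values.
_FISHER_REL_TOL = 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    With row and column margins fixed, enumerates every achievable table
    and sums the hypergeometric probabilities of all tables at most as
    probable as the observed one (the "sum of small p" two-sided
    convention).  A table with an empty margin carries no information and
    returns p = 1 with a warning.
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n < 1:
        raise ValueError("table is empty")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        logger.warning("degenerate 2x2 table (zero margin): p = 1")
        return 1.0
    # P(k in cell a | margins) via exact binomial coefficients.
    k_min, k_max = max(0, c1 - (n - r1)), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
        for k in range(k_min, k_max + 1)
    }
    p_obs = pmf[a]
    p = sum(pk for pk in pmf.values() if pk <= p_obs * (1 + _FISHER_REL_TOL))
    return min(p, 1.0)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve over distinct event times."""

    times: np.ndarray       # ascending distinct event times
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # number at risk at each event time
    n_events: np.ndarray    # events at each event time
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimator(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``events`` is 1 for an observed event, 0 for censoring.  Subjects
    censored exactly at an event time are counted at risk for that time
    (the standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= et).sum() for et in event_times])
    n_events = np.array([((t == et) & (e == 1)).sum() for et in event_times])
    if event_times.size:
        surv = np.cumprod(1.0 - n_events / n_at_risk)
    else:
        surv = np.array([])
    return KMCurve(event_times, surv, n_at_risk, n_events, n_total=t.size)


def median_survival(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple[float, float]:
    """k-group log-rank (Mantel-Cox) test.

    At each distinct event time the observed events per group are compared
    with their expectation under the null of identical hazards; the
    covariance of the observed counts is the multivariate hypergeometric
    one.  Ties are handled by the simultaneous-event convention and
    censored subjects at an event time remain at risk for it.  Returns
    (chi-square statistic with k-1 df, p-value).  If no events occur at
    all, returns (0, 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.size == e.size == g.size):
        raise ValueError("times, events and groups must have equal length")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 0.0, 1.0
    # Per-group membership matrix (n_subjects x k)
    member = g[:, None] == labels[None, :]
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n_j = (at_risk[:, None] & member).sum(axis=0).astype(float)
        dying = (t == et) & (e == 1)
        d = dying.sum()
        d_j = (dying[:, None] & member).sum(axis=0).astype(float)
        obs += d_j
        exp += d * n_j / n
        if n > 1:
            frac = n_j / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += v
    diff = (obs - exp)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df=k - 1))
    return stat, p


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p from the t-distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def tumor_volume(D: float, d: float, h: float) -> float:
    """Caliper tumor volume V = (D * d * h) / 6 in mm^3.

    D, d and h are the long diameter, short diameter and height in mm.
    """
    if not (D >= d > 0 and h > 0):
        raise ValueError("dimensions must satisfy D >= d > 0 and h > 0")
    return D * d * h / 6.0


def growth_fold_change(records: pd.DataFrame, animal: str) -> pd.Series:
    """Per-timepoint tumor-volume fold change vs day 0 for one animal.

    ``records`` needs columns animal, day, volume_mm3; a day-0 measurement
    must be present.
    """
    sub = records.loc[records["animal"] == animal].sort_values("day")
    if sub.empty:
        raise ValueError(f"no growth records for animal {animal!r}")
    day0 = sub.loc[sub["day"] == 0, "volume_mm3"]
    if day0.empty:
        raise ValueError(f"animal {animal!r} has no day-0 measurement")
    v0 = float(day0.iloc[0])
    fc = sub.set_index("day")["volume_mm3"] / v0
    fc.name = "fold_change"
    return fc


def arm_fold_changes(records: pd.DataFrame, arm: str, day: int) -> pd.DataFrame:
    """Mean +/- SEM fold change (vs day 0) across the animals of one arm."""
    sub = records.loc[records["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no records for arm {arm!r}")
    per_animal = [
        growth_fold_change(sub, a).get(day, np.nan) for a in sub["animal"].unique()
    ]
    per_animal = np.asarray(per_animal, dtype=float)
    per_animal = per_animal[~np.isnan(per_animal)]
    if per_animal.size == 0:
        raise ValueError(f"arm {arm!r} has no measurement at day {day}")
    sem = float(np.std(per_animal, ddof=1) / np.sqrt(per_animal.size)) if per_animal.size > 1 else float("nan")
    return pd.DataFrame(
        {"arm": [arm], "day": [day], "n": [per_animal.size],
         "mean_fold_change": [float(per_animal.mean())], "sem": [sem]}
    )


def arm_volume_ratio(
    records: pd.DataFrame, treated_arm: str, vehicle_arm: str, day: int
) -> float:
    """Ratio of mean treated to mean vehicle fold change at the given day.

    Each arm's fold changes are computed per animal against its own day-0
    volume; the ratio below 1 indicates growth inhibition by treatment.
    """
    treated = arm_fold_changes(records, treated_arm, day)
    vehicle = arm_fold_changes(records, vehicle_arm, day)
    return float(treated["mean_fold_change"].iloc[0] / vehicle["mean_fold_change"].iloc[0])
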