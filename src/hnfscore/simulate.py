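"""Synthetic cohorts with the statistical structure the analysis assumes.

Four generators emulate the study designs the pipeline is meant for:

* ``simulate_bulk_cohort`` — a bulk CRPC expression cohort with a latent
  HNF-high subgroup whose signature genes are shifted upward, whose
  response probability to AR-signaling inhibition is worse, and whose
  time-on-treatment / overall-survival hazard is multiplied.
* ``simulate_single_cell`` — negative-binomial single-cell counts for a
  vehicle and a treated condition, the treatment scaling down the HNF
  signature genes while leaving AR target genes untouched.
* ``simulate_ihc`` — multinomial stain-intensity counts whose strong /
  moderate probabilities rise monotonically with a linked per-sample
  score, plus binomial positive-cell counts.
* ``simulate_growth_curves`` — exponential xenograft growth per treatment
  arm starting at 100 mm^3 with lognormal measurement noise.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .scoring import ExpressionMatrix
from .signatures import ar_signature, hnf_signature

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "simulate_bulk_cohort",
    "simulate_single_cell",
    "simulate_ihc",
    "simulate_growth_curves",
    "DEFAULT_ARM_RATES",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic bulk cohort.

    Defaults echo the 25-patient enzalutamide-response cohort structure:
    ~20% of tumors harbor the GI program (latent high), with markedly
    higher non-response probability and a threefold hazard on treatment
    duration and survival.  ``signature_effect`` is the upward shift of
    each HNF signature gene in latent-high samples, in units of that
    gene's biological sd — the GI program is near-binary (essentially off
    in most tumors, strongly on in the high subset), hence a large
    default separation.
    """

    n_samples: int = 25
    frac_high: float = 0.2
    signature_effect: float = 3.0
    p_nonresponse_high: float = 0.8
    p_nonresponse_low: float = 0.15
    hazard_ratio_high: float = 3.0
    median_tot_months: float = 12.0
    median_os_months: float = 30.0
    censor_rate: float = 0.2
    n_background_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_high", "p_nonresponse_high", "p_nonresponse_low", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.frac_high < 1:
            raise ValueError("frac_high must lie in (0, 1)")
        if self.hazard_ratio_high <= 0:
            raise ValueError("hazard_ratio_high must be positive")
        if self.n_samples < 2 or self.n_background_genes < 0:
            raise ValueError("invalid cohort sizes")


@dataclass
class SyntheticCohort:
    """A simulated cohort: expression, latent truth and clinical outcomes."""

    matrix: ExpressionMatrix
    truth: pd.Series          # latent HNF-high indicator per sample
    outcomes: pd.DataFrame    # response + survival columns per sample
    spec: CohortSpec = field(repr=False, default=None)


def _gene_panel(n_background: int) -> list[str]:
    sigs = list(hnf_signature()) + [g for g in ar_signature()]
    background = [f"BG{i:04d}" for i in range(n_background)]
    return sigs + background


def simulate_bulk_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a bulk TPM cohort with a latent HNF-high subgroup.

    Per gene, log2 expression is Gaussian with its own baseline mean and
    sd; latent-high samples get ``signature_effect`` sd added to every HNF
    signature gene (the signature is a coherent regulon, so the shift acts
    jointly).  TPM values are ``2**x - 1`` (floored at 0), so the standard
    log2(TPM + 1) transform recovers the Gaussian scale.  Non-response is
    Bernoulli per latent class; time-on-treatment and overall survival are
    exponential with the latent-high hazard multiplied by
    ``hazard_ratio_high``; censoring is Bernoulli at ``censor_rate`` with
    a uniform fraction of the latent time observed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_panel(spec.n_background_genes)
    hnf_genes = list(hnf_signature())
    n_g, n_s = len(genes), spec.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n_s)]

    n_high = max(1, round(spec.frac_high * n_s))
    high = np.zeros(n_s, dtype=bool)
    high[rng.choice(n_s, size=n_high, replace=False)] = True

    mu = rng.normal(4.0, 1.0, size=n_g)
    sigma = rng.uniform(0.6, 1.2, size=n_g)
    x = rng.normal(mu[:, None], sigma[:, None], size=(n_g, n_s))
    hnf_idx = np.array([genes.index(g) for g in hnf_genes])
    x[np.ix_(hnf_idx, np.nonzero(high)[0])] += (
        spec.signature_effect * sigma[hnf_idx, None]
    )
    tpm = np.maximum(2.0 ** x - 1.0, 0.0)
    matrix = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples), scale="tpm")

    p_nr = np.where(high, spec.p_nonresponse_high, spec.p_nonresponse_low)
    nonresponder = rng.random(n_s) < p_nr
    hazard_mult = np.where(high, spec.hazard_ratio_high, 1.0)
    tot = rng.exponential(spec.median_tot_months / np.log(2.0) / hazard_mult)
    os_ = rng.exponential(spec.median_os_months / np.log(2.0) / hazard_mult)
    censored = rng.random(n_s) < spec.censor_rate
    frac_obs = rng.uniform(0.0, 1.0, size=n_s)
    outcomes = pd.DataFrame(
        {
            "sample": samples,
            "response": np.where(nonresponder, "nonresponder", "responder"),
            "tot_time": np.where(censored, tot * frac_obs, tot),
            "tot_event": (~censored).astype(int),
            "os_time": np.where(censored, os_ * frac_obs, os_),
            "os_event": (~censored).astype(int),
        }
    )
    truth = pd.Series(high, index=samples, name="latent_high")
    return SyntheticCohort(matrix=matrix, truth=truth, outcomes=outcomes, spec=spec)


def simulate_single_cell(
    n_cells_per_condition: int = 1000,
    treatment_hnf_downscale: float = 2.0,
    seed: int = 0,
    n_background_genes: int = 300,
    nb_dispersion: float = 0.1,
) -> AnnData:
    """Negative-binomial single-cell counts for vehicle vs treated tumors.

    Treated cells have every HNF signature gene's mean count divided by
    ``treatment_hnf_downscale``; AR target gene means are unchanged
    (mirroring BET-inhibitor treatment, which suppresses the GI program
    but not AR signaling).  Background genes carry most of the library
    depth, keeping the compositional coupling between the two signatures
    small.  ``nb_dispersion`` is the NB overdispersion alpha, with
    variance mu + alpha * mu^2.
    """
    if treatment_hnf_downscale <= 0:
        raise ValueError("treatment_hnf_downscale must be positive")
    if n_cells_per_condition < 2:
        raise ValueError("need at least 2 cells per condition")
    rng = np.random.default_rng(seed)
    hnf = list(hnf_signature())
    ar = list(ar_signature())
    background = [f"BG{i:04d}" for i in range(n_background_genes)]
    genes = hnf + ar + background
    n_g = len(genes)

    mean = np.empty(n_g)
    mean[: len(hnf)] = rng.uniform(1.0, 5.0, size=len(hnf))
    mean[len(hnf): len(hnf) + len(ar)] = rng.uniform(1.0, 5.0, size=len(ar))
    mean[len(hnf) + len(ar):] = rng.lognormal(np.log(5.0), 1.0, size=n_background_genes)

    def draw(mu_vec: np.ndarray, n_cells: int) -> np.ndarray:
        r = 1.0 / nb_dispersion
        p = r / (r + mu_vec)
        return rng.negative_binomial(r, p[None, :], size=(n_cells, n_g))

    vehicle = draw(mean, n_cells_per_condition)
    treated_mean = mean.copy()
    treated_mean[: len(hnf)] /= treatment_hnf_downscale
    treated = draw(treated_mean, n_cells_per_condition)

    counts = np.vstack([vehicle, treated])
    obs = pd.DataFrame(
        {
            "condition": ["vehicle"] * n_cells_per_condition
            + ["treated"] * n_cells_per_condition
        },
        index=[f"cell{i:05d}" for i in range(2 * n_cells_per_condition)],
    )
    var = pd.DataFrame(index=genes)
    return AnnData(counts.astype(np.int64), obs=obs, var=var)


def simulate_ihc(
    scores: np.ndarray,
    link_slope: float = 2.0,
    seed: int = 0,
    n_regions: int = 3,
    cells_per_region: int = 200,
    n_total_positive_assay: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stain-intensity count tables linked to per-sample scores.

    Each sample's scores are standardized to a latent intensity
    ``eta = link_slope * z(score)``; per region, nuclei fall into
    {negative, weak, moderate, strong} with ordered-logistic probabilities
    shifting toward strong as eta grows.  ``link_slope = 0`` is the flat
    (null) link.  Also returns a binomial positive-cell table (target
    5,000 cells counted per sample) with positivity probability rising in
    eta.  Returns ``(stain_counts, positive_counts)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("scores must be a 1-D array with >= 2 samples")
    if not np.isfinite(link_slope):
        raise ValueError("link_slope must be finite")
    rng = np.random.default_rng(seed)
    sd = scores.std()
    z = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    eta = link_slope * z
    cutpoints = np.array([-1.0, 0.5, 2.0])  # negative|weak|moderate|strong

    def expit(v):
        return 1.0 / (1.0 + np.exp(-v))

    rows = []
    for i, e in enumerate(eta):
        cdf = expit(cutpoints - e)          # P(category <= k)
        probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
        for r in range(n_regions):
            counts = rng.multinomial(cells_per_region, probs)
            rows.append(
                {
                    "region": f"S{i + 1:03d}_r{r + 1}",
                    "sample": f"S{i + 1:03d}",
                    "n_negative": counts[0],
                    "n_weak": counts[1],
                    "n_moderate": counts[2],
                    "n_strong": counts[3],
                }
            )
    stain = pd.DataFrame(rows)
    p_pos = expit(eta - 0.5)
    positives = pd.DataFrame(
        {
            "sample": [f"S{i + 1:03d}" for i in range(eta.size)],
            "condition": "na",
            "n_positive": rng.binomial(n_total_positive_assay, p_pos),
            "n_total": n_total_positive_assay,
        }
    )
    return stain, positives


DEFAULT_ARM_RATES = {
    # per-day exponential growth rates; vehicle doubles weekly
    "vehicle": np.log(2.0) / 7.0,
    "enzalutamide": 0.07,
    "pelabresib": 0.03,
    "combination": 0.0,
}


def simulate_growth_curves(
    arm_rates: dict[str, float] | None = None,
    n_animals: int = 5,
    days: tuple[int, ...] = (0, 7, 14, 21, 28),
    noise_sd: float = 0.1,
    seed: int = 0,
    start_volume: float = 100.0,
) -> pd.DataFrame:
    """Exponential xenograft growth per arm with lognormal noise.

    Treatment starts when tumors reach ~100 mm^3, so every animal starts
    at ``start_volume``; measured volume at day t is
    ``start_volume * exp(rate * t) * exp(N(0, noise_sd))``.
    """
    if arm_rates is None:
        arm_rates = DEFAULT_ARM_RATES
    if not arm_rates:
        raise ValueError("at least one treatment arm is required")
    if any(not np.isfinite(r) for r in arm_rates.values()):
        raise ValueError("growth rates must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for arm, rate in arm_rates.items():
        for i in range(n_animals):
            animal = f"{arm}_{i + 1}"
            noise = rng.normal(0.0, noise_sd, size=len(days))
            for day, nz in zip(days, noise):
                rows.append(
                    {
                        "animal": animal,
                        "arm": arm,
                        "day": int(day),
                        "volume_mm3": start_volume * np.exp(rate * day) * np.exp(nz),
                    }
                )
    return pd.DataFrame(rows)
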