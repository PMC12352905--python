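# Methods

## Signature scoring model

Expression is assumed to be quantified as transcripts per million (TPM).
Scores are computed on log2(TPM + pseudocount) with pseudocount 1 by
default; matrices already on the log scale can be passed with
`scale="log2tpm"`. Each gene is z-scored across the samples of the
provided matrix — the cohort itself is the reference population, so a
score is only comparable within the cohort it was computed in. The
sample standard deviation (ddof = 1) is used. Genes whose values are
identical across all samples get z = 0 with a logged warning rather
than NaN; constancy is detected by exact value range rather than a
computed sd, because the two-pass sd of identical floats can round to a
tiny nonzero number and turn 0/0 into arbitrary pseudo-z values.

A signature score is the plain sum of z over the signature's genes.
Signature genes missing from the matrix are dropped with a warning and
recorded per sample (`n_genes_used`, `missing_genes`) by default
(`drop_warn`), because real matrices lose symbols to annotation drift;
`missing_policy="error"` enforces completeness. Gene symbols are matched
case-insensitively after trimming; duplicate symbols in an input matrix
are rejected outright rather than aggregated.

Stratification uses fixed, configurable thresholds: score ≥ 12 High,
≤ 0 Low, otherwise Intermediate. The boundary is inclusive at 12. A
two-level mode labels every non-High sample Low, for cohorts analyzed as
High versus rest. The HNF score is a sum of 11 z-scores, so under a null
cohort it has mean 0 and sd ≤ √11 ≈ 3.3; a threshold of 12 sits several
null-sd out and selects only samples with a coherently elevated panel.

The AR panel is the de-duplicated, order-preserving union of two source
signatures. The published source lists are not redistributable here, so
the package ships clearly labelled placeholder lists of canonical AR
target genes; any GMT file can be substituted at every entry point, and
`hnfscore export-gmt` writes the built-ins for editing.

## Outcome statistics

These estimators are implemented in the package rather than delegated,
because their conventions are part of the analysis contract; the test
suite cross-checks each against an independent implementation
(scipy for Fisher, lifelines for Kaplan–Meier and log-rank).

**Fisher's exact test (2×2).** With margins fixed, the probability of
each achievable table is hypergeometric, computed from exact binomial
coefficients. The two-sided p is the sum over tables whose probability
does not exceed the observed table's, with a 1e-7 relative guard against
float ties ("sum of small p" convention — the one under which the
High 4/1 vs Low 3/17 response table yields p = 0.0123 ≈ 0.012). A table
with an empty margin returns p = 1 with a warning.

**Kaplan–Meier.** Product-limit estimate over distinct event times;
subjects censored exactly at an event time are counted at risk for that
time. Median survival is the smallest t with S(t) ≤ 0.5 and is reported
as undefined when the curve never reaches 0.5.

**Log-rank (Mantel–Cox), k ≥ 2 groups.** At each distinct event time
the per-group observed events are compared with their expectation under
equal hazards; the covariance is multivariate hypergeometric with the
d(n−d)/(n−1) tie correction, ties handled by the simultaneous-event
convention. The statistic uses the first k−1 groups against the
pseudo-inverse-backed solve of their covariance block, with k−1 degrees
of freedom. All-censored input returns (0, 1).

**Pearson correlation and Welch's t** are standard steps and delegate
to scipy.stats (t-distribution p with n−2 df; unequal-variance t for the
single-cell condition comparison).

**Tumor volume** is V = (D·d·h)/6 mm³ from long diameter, short
diameter and height; fold change is per animal versus its own day-0
volume, arm summaries are mean ± SEM (ddof = 1), and the
treated/vehicle ratio divides the two arm means at a common day.

## IHC H-score

H = 100·(1·%weak + 2·%moderate + 3·%strong), with percentages taken
over all counted nuclei including negative ones, giving the
conventional 0–300 range; H = 300 exactly when every nucleus stains
strongly. Applying the weights to percentages rather than raw nuclei
counts makes regions of different cellularity comparable and keeps the
score bounded. Per-sample values are unweighted means over regions with
SEM (ddof = 1, undefined for a single region). Intensity binning
(weak/moderate/strong) is an upstream image-analysis choice; the module
consumes pre-binned counts only.

## Single-cell scoring

Counts are normalized per cell to `log(1 + scale·count/total)` with
scale 10,000 by default (counts-per-10k + log1p); cells with zero total
counts are rejected by ID. The exact normalization used upstream of any
particular dataset may differ; the scale is configurable and the choice
matters little for a sum-z score, which is location/scale-normalized
per gene anyway. Genes are z-scored across the pooled cells of **all**
conditions — a per-condition reference would absorb exactly the
treatment shift the condition comparison measures. Pseudobulk profiles
are raw-count sums per condition and conserve the grand total exactly.
Proliferation or senescence programs can be scored with the same
machinery by supplying the gene lists as GMT input. Clustering,
embedding and QC filtering are out of scope; cluster labels are
accepted as metadata if present.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes, so every stage is testable without access to patient
data. They are pure functions of their parameters and seed.

**Bulk cohort.** Per-gene log2 expression is Gaussian with per-gene
baseline mean ~ N(4, 1) and sd ~ U(0.6, 1.2); TPM = 2^x − 1 floored at
0, so the standard log2(TPM+1) transform recovers the Gaussian scale.
Defaults: 25 samples, 20% latent HNF-high, 200 background genes.
Latent-high samples have every HNF signature gene shifted up by
`signature_effect` gene-sds jointly — the signature models a coherent
regulon, so the shift is not per-gene independent. The default effect is
3 sd: the GI program is near-binary (essentially off in most CRPC
tumors, strongly on in the high subset), and 3 sd makes the expected
high-sample score ≈ 17 against a sum-noise sd ≈ 2, placing High samples
clearly above the fixed threshold of 12 the analysis uses — mirroring
the clean visual separation the score produces on real cohorts. Weaker
settings (≈ 2 sd) put expected stratification sensitivity near 0.75 and
are useful for studying the threshold's behavior, not as the default
condition. Non-response is Bernoulli (0.8 high / 0.15 low, echoing the
4-of-5 versus 3-of-20 structure of the 25-patient cohort);
time-on-treatment and survival are exponential with baseline medians 12
and 30 months and a ×3 hazard for latent-high samples; censoring is
Bernoulli at rate 0.2 with a uniform fraction of the latent time
observed.

**Single cell.** Negative-binomial counts (overdispersion α = 0.1, so
variance μ + αμ²), 1,000 cells per condition by default. Signature-gene
mean counts are U(1, 5); background means are lognormal(ln 5, 1) over
300 genes, so library depth is dominated by background and the
compositional coupling between the HNF and AR scores stays small when
treatment halves the HNF genes. Treated cells divide every HNF gene
mean by `treatment_hnf_downscale`; AR genes are untouched.

**IHC.** Given linked per-sample scores, a latent intensity
η = slope·z(score) shifts ordered-logistic category probabilities
(cutpoints −1, 0.5, 2) toward strong staining; regions are multinomial
draws of 200 nuclei, three regions per sample. Positive-cell counts are
binomial over 5,000 cells with positivity expit(η − 0.5). Slope 0 is
the null (flat) link.

**Growth curves.** V(t) = 100·exp(rate·t)·exp(N(0, noise_sd)) per
animal and timepoint, five animals per arm, measured twice weekly over
four weeks. Default per-day rates: vehicle ln2/7 (weekly doubling),
enzalutamide 0.07, pelabresib 0.03, combination 0.

What the generators do **not** emulate: realistic transcriptome-wide
covariance, batch effects, mouse-read contamination, doublets, or
cohort heterogeneity in censoring mechanisms. Passing tests on this
synthetic structure demonstrates that the estimators and the recovery
logic are correct under the assumed model, not that the biological
claims replicate on new patient data.

## Verification conditions and numerical choices

The test suite and acceptance script use these problem sizes: log-rank
null calibration over 2,000 two-group exponential datasets (n = 50 per
group, all events) with rejection rate required in [0.03, 0.07] at
α = 0.05, and power > 0.5 at hazard ratio 3 with 15 per group over
1,000 datasets; cohort recovery over 200 replicates of the default
25-sample cohort (stratification sensitivity ≥ 0.8, High-vs-rest Fisher
p < 0.05 in the majority); the single-cell null false-positive rate
over 600 replicate null datasets of 1,000 cells per condition (≤ 7% —
600 replicates keep the estimate's own sampling noise well inside the
band); Fisher enumeration equivalence over every 2×2 table with
N ≤ 30. The growth-ratio recovery reported by the acceptance script is
the mean relative error over 20 replicate 5-animal experiments, since a
single experiment's error at noise sd 0.1 has a long tail (p90 ≈ 15%).

Degenerate inputs are rejected early with messages naming the offending
gene, sample, cell or line: negative TPM, duplicate symbols,
single-sample z-scoring, zero-count cells, empty regions, missing day-0
measurements, non-increasing measurement days. Warnings (missing or
constant genes, degenerate Fisher tables) go through the `logging`
machinery and are never swallowed.

## Known limitations

- Scores are cohort-relative; there is no cross-cohort calibration or
  batch correction, and absolute thresholds (12 / 0) assume a cohort of
  broadly comparable composition to those the thresholds were derived
  on.
- The shipped AR gene lists are placeholders; results for the AR score
  are only meaningful after substituting the intended published lists.
- No Cox modeling, multiple-testing correction, clustering or
  differential-expression machinery — by design, these live upstream or
  downstream of this package.
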