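# Methods

This note records the statistical model behind each module, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## MSI scoring

The detector works on per-locus read-length histograms: for a locus with
reference STR tract length `r` bp, a read of tract length `l` is counted as
altered when `l ≤ r − 2` (shortened by **at least** 2 bp) or `l > r`
(lengthened by any amount). Two readings of "shortened by 2 bp" are possible —
at-least-2 and exactly-2 — and both are implemented behind
`msi.AlterationRule`; at-least-2 is the default because somatic deletions at
microsatellites remove whole repeat units (two or more bases at the clinically
archetypal mononucleotide markers), so deeper deletions must keep counting.
One-bp shortenings are excluded deliberately: PCR stutter at mononucleotide
repeats places substantial mass at `r − 1` even in stable samples, and
counting it would destroy specificity. Lengthenings of any size count
(`count_lengthening=False` switches this off).

The MSI score is the **sum** of per-locus alteration prevalences over
evaluable loci (range `[0, n_loci]`); a normalized score (sum / n loci) is
also reported so samples with dropped-out loci remain comparable, but the raw
sum is the primary quantity. Loci with zero depth are excluded rather than
imputed, and `n_loci_evaluated` is reported; calls require at least
`min_loci = 10` evaluable loci, otherwise the result is *indeterminate*.

No public numeric positivity cutoff exists for this score, so the threshold
is calibrated on stable reference samples: default mean + 3 SD of reference
scores (a percentile rule is selectable). Positivity is **strict** —
`score > threshold`; a tie is called MSS, the conservative direction for a
treatment-selection biomarker.

## MSI clonality

Clonality quantifies the MSI-bearing fraction — of tumor cells in FFPE, of
cell-free DNA in plasma. Per locus the *area above the reference* is
`Σ_bins max(0, p_sample(l) − envelope(l))`, the sample mass exceeding a
reference envelope; `s` is the mean over evaluable loci, and

    clonality% = clamp(88.81·s − 11.42, 0, 100).

The envelope rule is genuinely underdetermined (excess over the pooled
reference, the per-bin mean, or the per-bin maximum all fit the phrase "area
above the reference distributions"); the default is the **per-bin maximum**
across references — excess over anything a stable sample ever shows — with
`mean` and `mean_2sd` selectable. The maximum rule makes the estimator
conservative: a fresh stable sample almost never exceeds the envelope, so the
negative intercept clamps its clonality to exactly 0.

The transform's coefficients imply `s ∈ [0, 1]` (clonality tops out at 77.4%
at `s = 1`); inputs outside `[0, 1]` are rejected, outputs clamped to
`[0, 100]` because clonality is a percentage. Dichotomization: FFPE high at
≥ 18%, LB high at ≥ 7%, boundary inclusive. The composite-score predictor for
tissue uses a *different* constant, ≤ 15% — both constants are named
separately (`clonality.FFPE_HIGH_THRESHOLD` vs
`outcomes.FFPE_LOW_CLONALITY_PREDICTOR`) because the dichotomization and the
composite predictor are distinct definitions, not one threshold. Clonality is
interpreted only for samples called MSI-positive; for MSS samples the class is
`not_applicable` (the value is still computed for inspection).

## Concordance

dMMR by IHC and MSI by PCR/NGS are one binary phenotype for agreement
purposes. Missing results are handled complete-case per statistic: pairwise
deletion for pairwise rates and Cohen's kappa, listwise deletion for Fleiss's
kappa and the all-method agreement rate — so each statistic has its own
denominator, as in real cohorts with method-specific dropout. Cohen's kappa
uses marginal-product chance agreement and is reported as undefined (None)
when chance agreement is 1 (e.g. every sample positive by both methods — a
real situation here, since cohorts are enriched for MSI-positive patients).
Fleiss's kappa is delegated to `statsmodels`.

The discordance predictor compares IHC against the genomic methods (PCR,
NGS-FFPE, NGS-LB): by default a patient is discordant when IHC differs from
**any** available genomic call (`mode="all"` requires all to differ). The ANY
reading matches partial discordance patterns — e.g. IHC+ with MSS liquid
biopsy only — being clinically meaningful.

## Exact response statistics

ORR = CR+PR and DCR = CR+PR+SD over the intention-to-treat denominator;
non-evaluable patients stay in the denominator. Clopper–Pearson bounds come
from Beta quantiles (`lo = B(α/2; x, n−x+1)`, `hi = B(1−α/2; x+1, n−x)`),
exact at the boundaries (0 at `x=0`, 100 at `x=n`). Values are stored at full
precision; 1-decimal rounding is applied only for display.

Barnard's unconditional exact test is implemented directly: all outcomes with
the observed group sizes are enumerated, ordered by the absolute pooled score
statistic `(p̂₁−p̂₂)/√(p̄(1−p̄)(1/n₁+1/n₂))` (defined 0 when the pooled
estimate is 0 or 1), and the two-sided p-value is the maximum over a fixed
grid of 1001 equally spaced interior nuisance probabilities of the extreme-set
probability. The grid size is exposed because "Barnard's test" names a family;
1001 points make the grid error negligible at the sample sizes involved.
Degenerate margins give p = 1. `scipy.stats.barnard_exact` (which optimizes
the nuisance continuously) agrees to ~1e−5 and serves as an independent
cross-check in the tests; Fisher's exact test is scipy's.

## Survival

Kaplan–Meier estimation and Weibull AFT regression are delegated to
`lifelines`; this package adds covariate scaling, the hazard-ratio report and
penalizer selection. "Scaled beforehand" is applied to continuous covariates
(z-score); binary covariates stay 0/1 for interpretability, with a flag to
scale everything. Zero-variance covariates are dropped with a warning;
patients missing a covariate are dropped listwise.

The model is AFT but effects are reported as hazard ratios using the Weibull
AFT↔PH equivalence `HR_j = exp(−k·β_j)`; the time-ratio report `exp(β_j)` is
available via `report="time_ratio"`. HR confidence bounds transform the Wald
CI of `β_j` through the same map (conditioning on the fitted shape `k`; the
extra variance from estimating `k` is not propagated — a known limitation).

Penalizer selection fits the model at each λ in a default grid
{0, 0.001, 0.01, 0.1, 1} and keeps the λ minimizing
`AIC = 2·(p+2) − 2·ℓ(θ̂_λ)`, where `ℓ` is the **unpenalized** log-likelihood
at the penalized estimates and p+2 counts covariate coefficients plus scale
and shape. Exact ties go to the smallest λ; fits that fail to converge at one
λ are skipped (an error is raised only if all fail).

## Synthetic data

The generator emulates the study conditions end to end: a 39-locus STR panel
(mostly mononucleotide A/T runs of 12–27 units, one in five a dinucleotide),
400 stable reference profiles, and 5000× per-locus depth, all from one seed
through spawned sub-streams (adding a stage never perturbs earlier draws;
identical seeds give identical bytes).

* **Stutter**: each read shifts by whole repeat units with probability 0.02,
  direction symmetric, step count geometric (p = 0.8) — the standard
  single-step-dominated PCR stutter approximation. Observed counts are one
  exact multinomial draw per locus, so per-locus depth is exactly the
  configured depth.
* **MSI clone**: per locus per sample the clone allele deletes `d ≥ 2` repeat
  units, `d = 2 +` a shifted geometric with mean 3 units total. The ≥ 2 floor
  makes clone reads visible to the ≥ 2 bp detector at mononucleotide loci.
* **Samples**: reads are a binomial mixture — clone allele with probability
  equal to the clone fraction, stable allele otherwise, stutter on both.
* **Cohort**: every patient is truly MSI-positive (the inclusion criterion of
  the emulated design). FFPE clone fractions are Beta(2,2) rescaled to
  (0.05, 0.95); LB fractions multiply the FFPE fraction by a lognormal ctDNA
  factor (log-mean log 0.05, log-SD 1.5), reflecting the large variability of
  ctDNA shedding and producing a realistic minority of MSS liquid biopsies.
  IHC/PCR calls apply per-method false-negative/positive rates (defaults
  0.15/0.02 and 0.05/0.01) and per-method missingness (0.25, 0.03, 0.20,
  0.07) so denominators vary per statistic; **NGS calls are produced by
  actually running the caller on generated profiles**, never by shortcutting
  the measurement model. Response is logistic on the four composite-score
  predictors (intercept 0.7, weight −1.5 each — a testing scaffold, not an
  estimated model); PFS is Weibull (shape 1.3, baseline scale e^{log 250}
  days) on the true dichotomized predictors, with administrative censoring of
  20% of subjects at a uniform fraction of their event time.

What the generator does **not** emulate: sequencing substitution errors, locus
dropout correlated with fixation quality, multiple MSI subclones, tumor-purity
effects on FFPE, inter-locus dependence, and real inter-patient covariate
correlation structure. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model — monotone score response,
parameter recovery, calibrated intervals — not clinical performance on real
specimens.

## Problem sizes used in tests and the acceptance script

Unit tests run on down-scaled conditions (8–10 loci, 25–30 references, depth
400–2000). Study-scale checks use the full 39-locus/400-reference/5000×
conditions: operating characteristics on 200 samples per arm, clonality
recovery on 8 clone-fraction levels × 50 samples, AFT recovery on 100
replicates of n = 1000 per configured hazard ratio (25 replicates in the
acceptance script, which reports the median), and an end-to-end cohort of 60
patients — 60 rather than 30 so the multivariate AFT fit is routinely
well-conditioned while remaining the same order of magnitude as the emulated
study.

## Known limitations

* The clonality transform's coefficients are taken as fixed calibration
  constants; the package does not refit them.
* Kappa statistics are unstable under the extreme marginals typical of
  all-comers-positive cohorts; they are reported with their denominators and
  should be read alongside raw agreement.
* Barnard's test cost grows with the product of group sizes; it is intended
  for the small per-arm counts of early-phase cohorts.
* HR confidence intervals condition on the fitted Weibull shape.
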