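# msikit

Microsatellite instability (MSI) analysis from amplicon NGS, and the outcome
statistics that go with it, for studies of MSI/dMMR colorectal cancer treated
with immune checkpoint inhibitors.

`msikit` is aimed at bioinformaticians and biostatisticians who work with
STR (short tandem repeat) read-length histograms from targeted panels and
need, in one tested package:

* an **MSI caller** operating on per-locus STR length histograms,
* a quantitative **MSI clonality** estimate (the MSI-bearing tumor-cell or
  ctDNA fraction) for FFPE tissue and liquid biopsy (LB),
* **concordance analysis** across determination methods (IHC, PCR, NGS on
  FFPE, NGS on LB): concordance rates, Cohen's and Fleiss's kappas,
* **exact response statistics**: Clopper–Pearson intervals, Barnard's
  unconditional and Fisher's conditional exact tests, and a composite
  non-responder score,
* penalized **Weibull AFT survival modelling** with AIC-based penalizer
  selection,
* a **synthetic-data generator** that emulates the whole study — stutter-noised
  STR profiles, clone mixtures, assay error, logistic response, Weibull PFS —
  so every stage is testable without patient data.

## The model

**MSI score.** At each panel locus with reference tract length `r` (bp), a read
of observed tract length `l` is *altered* when `l ≤ r − 2` or `l > r`
(one-bp shortenings are treated as PCR stutter and ignored). The per-locus
alteration prevalence is the altered fraction of reads, and the sample's MSI
score is the cumulative prevalence across all evaluable loci:

```
score = Σ_j  #\{reads at locus j: l ≤ r_j − 2 or l > r_j\} / depth_j
```

A sample is MSI-positive when its score strictly exceeds a threshold
calibrated on stable reference samples (default: mean + 3 SD of reference
scores).

**MSI clonality.** Per locus, the *area above the reference* is the
probability mass by which the sample's length distribution exceeds a
per-length-bin envelope built from the reference set (default: per-bin
maximum). With `s` the mean area over loci, percent clonality is the fitted
linear transform

```
clonality% = clamp(88.81 · s − 11.42, 0, 100)
```

dichotomized as high at ≥ 18% for FFPE and ≥ 7% for LB samples.

**Composite non-responder score.** A patient is flagged when at least two of
{IHC-vs-genomic discordance, MSS liquid biopsy, FFPE clonality ≤ 15%,
LB clonality ≥ 7%} are present, or when LB clonality alone is ≥ 10%.

**Survival.** PFS follows a Weibull accelerated failure time model
`log T = β₀ + x'β + σ·ε` with L2 penalty on `β`, the penalizer selected by AIC
over a grid; hazard ratios use the Weibull AFT↔PH equivalence
`HR_j = exp(−k·β_j)` with `k` the fitted shape.

## Worked example

Simulate a 25-patient study (39 STR loci, 400 stable references, 5000×
depth), call MSI, estimate clonality, and summarize:

```sh
msikit --seed 5 simulate --out-dir study --n-patients 25
msikit msi-call --panel study/panel.tsv --histograms study/histograms.tsv \
    --references study/references.tsv --out msi_calls.csv
msikit concordance --cohort study/cohort.csv --out-dir conc
msikit outcomes --cohort study/cohort.csv --out outcomes.json
msikit survival --cohort study/cohort.csv --out-dir surv
```

which prints:

```
wrote synthetic study (25 patients) to study
called 45 samples (threshold 0.5540) -> msi_calls.csv
{
  "fleiss_kappa": -0.06666666666666667,
  "overall_agreement": 0.75,
  "n_complete": 16
}
ORR 40.0% (95% CI 21.1-61.3%), DCR 44.0% (95% CI 24.4-65.1%)
AFT fit: penalizer 0.0, AIC 166.51 -> surv/aft_table.csv
```

Reading: 45 samples (FFPE + LB; some assays are missing by design) were
scored against a reference-calibrated positivity threshold of 0.554. Of the
16 patients with all four method results, 75% were called concordantly by
all methods (Fleiss κ ≈ −0.07 — in a cohort where nearly everyone is truly
MSI-positive, marginals are extreme and kappa is near or below zero even at
high raw agreement). The ITT objective response rate was 40% with its exact
binomial CI, and the Weibull AFT fit selected no penalty on this
well-conditioned cohort.

The same analyses are available as a library (`msikit.msi`,
`msikit.clonality`, `msikit.concordance`, `msikit.outcomes`,
`msikit.survival`, `msikit.synthetic_data`); see the docstrings and
`docs/methods.md`.

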