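# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. It is written for an analyst who wants to
know exactly what each stage computes and what the synthetic validation
does and does not demonstrate.

## Synthetic cohort model

The generator (`jnksig.synthio`) emulates the statistical structure the
analysis pipeline assumes, not any particular dataset.

**Expression.** Gene g has baseline log2 mean μ_g ~ Uniform(5, 9) and
per-gene biological standard deviation 1.0 on the log2 scale (typical
interquartile dynamics of bulk RNA-seq after normalisation). For the
`n_signal_genes` signal genes the standardised noise is
ρ·z + √(1−ρ²)·ε, where z is the latent phospho level (z-scaled across
the cohort), so log-expression correlates with z at Pearson ρ
(`signal_correlation`, default 0.5 — a realistic RNA-to-phosphoprotein
coupling; perfect correlation would make the derivation problem
trivial). Subtype marker genes — disjoint blocks of 20 positive and 20
negative markers per subtype, also disjoint from the signal genes — are
shifted ±`centroid_shift` (default 1.0 log2 units) in samples of that
subtype. Counts are Poisson around 2^(log2x) times a log-normal
library-size factor (σ = 0.35), which makes the raw matrices behave like
count data: sample-level read-count failures for the QC filter, zeros
for the prevalence filter, and mild attenuation of the target
correlation.

**Subtype mix.** Default proportions follow the published five-subtype
counts of the trial cohort this pipeline was designed around
(BL 72, IM 86, M 89, LAR 47, MSL 53 of 347); BL2 has probability 0 by
default but can be given mass to exercise the reassignment rule.

**Clinical covariates.** Treatment is 1:1 CM vs no-CM. TILs are normal
(mean 40%, sd 15% for IM; 15%, 10% otherwise; clipped to [0, 100]),
reproducing the known association between the immunomodulatory subtype
and lymphocyte infiltration. Stratification factors (tumor size T1/T2/T3,
nodal N0/N1–3/N4+, four age bins) are drawn with plausible adjuvant-trial
frequencies; they do not enter the hazard by default.

**Survival.** The base event process (DFS) is exponential with rate
`baseline_hazard`·exp(η) per month, baseline 0.004/month (≈78% 5-year
survival). η is assembled from `log_hr_effects`, a map from covariate
terms — `pjnk`, `treatment`, `tils`, `subtype_<NAME>`, and products
`a:b` — to log hazard ratios. Defaults encode the effect sizes the
pipeline is meant to detect: a weak adverse pJNK main effect
(log 1.29) and a strong protective IM × pJNK interaction (log 0.17).
Censoring is administrative: C ~ Uniform(0, τ) with τ solved by
bisection so the expected censoring fraction hits `censoring_rate`
(default 0.8, matching a ≈19% event rate; `censoring_rate=0` disables
censoring entirely). BCFI, DRFI and OS are thinned copies of DFS — a DFS
event is also an event for the nested endpoint with probability 0.8,
0.6, 0.5 respectively, otherwise censored at the DFS time. Thinning
preserves every log hazard ratio exactly and keeps the endpoint nesting
(every BCFI event is a DFS event) without modelling each clinical
transition.

**Case-cohort sampling.** Cases are BCFI events; all are included with
sampling fraction 1. Non-cases are sampled without replacement within
strata formed by the full cross of the four stratification factors
(× case status for bookkeeping; empty cells simply contribute no
stratum). The non-case target `round(ratio × n_cases)` (ratio default 3)
is apportioned to strata by largest remainder, capped at stratum size
and floored at one draw per non-empty stratum — the floor guarantees
every non-case a positive inclusion probability, without which
Horvitz–Thompson weighting would be biased (we observed ≈0.06 log-HR
bias without it). Per-stratum fractions are recorded; weights are their
inverses, so cases carry weight exactly 1.

**What the generator does not emulate:** FFPE degradation beyond low
read counts, batch effects, realistic proteomics noise, competing risks,
or covariate-dependent censoring. Passing tests therefore demonstrate
correctness of the estimators and procedures under the assumed model,
not robustness to those real-data pathologies.

## Preprocessing

Samples with column sums below 200,000 counts are dropped (column sums
proxy reads mapped to the transcriptome); then genes detected (count
> 0) in fewer than ceil(0.70 · n) samples are dropped — samples first,
then genes, since the prevalence denominator changes with the sample
set. "Expressed" means a non-zero count. Normalisation is
log2(CPM + 1); the pipeline's downstream uses are correlation- and
z-score-based, for which log-CPM is rank-stable against
variance-stabilising alternatives. z-scaling uses the unbiased (n−1)
standard deviation everywhere in the package; zero-variance genes are
excluded from scaling and reported.

## Signature derivation

Training/test splitting is a seeded permutation with
round(train_fraction · n) training samples (default fraction 95/141).
Stability selection draws `n_iterations` = 1000 subsamples of
round(n/3) samples (floor 3, without replacement); per draw, each
gene's Pearson r with the response is computed, with zero-variance
genes contributing r = 0 for that draw; selection requires |r| > 0.25
(strict) in ≥ 75% of draws. The elastic net minimises
(1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) with α = 0.5 on genes
z-scored with training statistics (recorded in the signature metadata
and reused for test-set scoring; validating with test-cohort
re-normalisation is available as a flag). The λ grid is 100 log-spaced
points from λ_max = max|Xᵀ(y−ȳ)|/(n·α) down to 10⁻⁴ λ_max; λ is chosen
by minimum mean 7-fold CV squared error, ties resolved toward the
larger (sparser) λ. Genes with zero coefficient at the chosen λ are
dropped; an all-zero fit is an explicit error. Held-out validation
reports Pearson r and its two-sided p; train/test overlap is a hard
error.

A sizing note for the recovery benchmark: the effective |r| needed for
selection is roughly 0.25 + 0.675·σ_draw, where σ_draw ≈
√(1/m − 1/n) is the finite-population spread of a subsample's r around
the full-sample value. With ~80 training samples null genes clear this
hurdle at a few per thousand — enough to contaminate a 25-gene candidate
set by ~10% — whereas at 120 derivation samples contamination drops
to well under 5%. The recovery benchmark therefore derives on 120
samples and validates on 40 additional held-out samples (cohort 160);
measured over 10 cohorts: recall 0.99, contamination 0.4%, held-out
r 0.91.

## Scoring and grouping

Scores are the mean over signature genes of coefficient × z-expression,
computed within the scored cohort unless frozen training statistics are
supplied. Missing signature genes are dropped with a warning (error at
zero overlap). Median dichotomisation labels score ≤ median as "low" —
the low/high quotes in the source convention leave equality unaddressed,
and assigning ties low is conservative for the high-risk group. Gene-set
scores are per-sample medians of the set's (log) expression — a
deliberate, transparent substitute for deconvolution-based abundances —
and the effector/suppressor contrast is a guarded ratio for abundance
scores or a difference for log-scale scores.

## Subtyping and TIME classes

Subtype scores center/scale each gene across the full scored cohort
(consistent with per-dataset normalisation elsewhere in the package).
Argmax ties are broken by the fixed order BL1, IM, M, LAR, MSL, BL2
(BL2 last so a tie can never resurrect it) and flagged. The TIME
classifier is a transparent two-axis threshold scheme over z-scaled
immune and stromal gene-set median scores (immune-high → FI; immune-low
& stroma-high → SR; both low → MR; within ±δ of the governing threshold
→ unclassified, δ default 0.25) — the original spatially derived
classification is not recoverable from published material, so this is a
configurable stand-in, not a reproduction. The pipeline uses the IM-up
markers as the immune set and the MSL-up markers as the stromal set on
synthetic data.

## Weighted survival analysis

The weighted Kaplan–Meier estimator uses weighted event and at-risk
sums; unit weights give the classical estimator, and integer weights
equal row duplication exactly. The weighted Cox fitter maximises the
weighted Breslow partial likelihood by Newton–Raphson with step-halving
(convergence: Δloglik < 1e-10 and max |score| < 1e-6; a coefficient
diverging past ‖β‖ > 100 raises a monotone-likelihood error). Breslow
tie handling is the only option — it is what makes integer weights
exactly equivalent to duplicated rows, the contract the tests enforce;
an Efron request raises. Robust Lin–Wei sandwich standard errors (dfbeta
cross-products with weights) are the default because sampling weights
invalidate the model-based variance; the implementation reproduces R
`survival::coxph(weights=, robust=TRUE, ties="breslow")` to 7 digits on
tied, weighted fixtures. The likelihood-ratio p for a declared feature
of interest compares nested weighted log partial likelihoods — with
weights this is a quasi-LR and is labelled as such. Interaction results
report exp(β_interaction), identical by construction to the ratio of the
stratum-specific hazard ratios from the same fit, with a Wald p from the
robust SE. CI level is fixed at 95% on the log-HR scale. BH adjustment
is applied within each endpoint's family of subtype-interaction tests.

Calibration, measured at the n = 600 study conditions over 1000 null
replicates: the full-cohort interaction Wald test rejects at 0.038–0.042
(nominal 5%; slightly conservative because the interaction cell carries
few events), and the Horvitz–Thompson weighted case-cohort variant at
0.034–0.037. The weighted variant's extra conservatism is the expected
behaviour of the plain sandwich under finite-population stratified
sampling — it over-estimates the variance relative to the
Prentice/Barlow case-cohort refinements, which are deliberately out of
scope. The bias is protective (never anticonservative in our
experiments); users wanting exact case-cohort variances should export
the fits to specialised software.

## Pipeline and reproducibility

`run_full_pipeline` executes simulate/load → QC → derivation (or
signature loading) → scoring and median split → subtype/TIME calls →
immune-related flag (IM subtype or TILs strictly > 30%, rule
configurable) → case-cohort weighting → per-endpoint weighted Cox
interaction models (adjusted for tumor size > 2 cm, nodal involvement
and treatment arm) with BH q values → weighted KM with a 60-month
estimate. Sub-model fits that are unidentifiable on the sampled data
(constant indicators, fewer events than parameters, quasi-separation —
flagged when the interaction coefficient or its SE exceeds 10) are
recorded as skipped rather than reported as spurious extremes. All
stage seeds are fixed offsets of the single pipeline seed, and the
serialized report is byte-identical across reruns; reports carry a
config hash, the seed and the package version.

The validation suite and acceptance script size their simulations to
run comfortably on one CPU: 10 derivation cohorts of 160 × 2000, 200
bias replicates and 1000 calibration replicates at n = 600 — large
enough that the Monte-Carlo error of each reported quantity is small
relative to its acceptance margin.

## Known limitations

* The TIME classifier is a configurable surrogate, not the original
  histology-anchored method.
* The generator's endpoint thinning gives nested endpoints identical
  event times; analyses that depend on the gap between, say, distant
  recurrence and death need a richer multistate model.
* Case-cohort variance uses the plain sandwich (see above).
* No time-varying covariates or competing risks.
* The elastic net assumes a Gaussian response; classification responses
  are out of scope.
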