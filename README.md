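# jnksig

Derivation and scoring of a phospho-JNK (pJNK) transcriptional signature,
triple-negative breast cancer (TNBC) molecular subtyping, and case-cohort
weighted survival analysis with subtype × biomarker × treatment interaction
testing — packaged as a tested, reusable pipeline with a synthetic cohort
generator so every stage can be validated end to end without access to
controlled trial or consortium data.

## Who this is for

Translational biomarker analysts working with bulk RNA-seq from adjuvant
trial cohorts who need to (a) build an expression surrogate for a
phospho-protein level from matched RNA-seq/proteomics data, (b) apply
centroid-based TNBC molecular subtyping, and (c) analyse outcomes under a
stratified case-cohort sampling design with inverse-probability weighting.

## The methods at the core

**Signature derivation** (`jnksig.sigderive`). On a training cohort with a
continuous phospho response *y*, candidate genes are found by stability
selection: 1000 random subsamples of one third of the training samples are
drawn, and a gene is a candidate iff its Pearson correlation with *y*
satisfies |r| > 0.25 in at least 75% of the draws. Candidates enter an
elastic net (mixing α = 0.5) over a 100-point λ grid with 7-fold CV
(minimum mean squared error), and the genes with non-zero coefficients β
form the signature. A sample's score is

    score_j = mean_g ( β_g · z_gj )

where z is the per-gene z-scored log2 expression; cohorts are split into
low/high pJNK groups at the median score (ties low).

**Subtyping** (`jnksig.subtype`). Per subtype s with positive/negative
marker sets, score(s, j) = mean z of positive genes − mean z of negative
genes; the argmax subtype is called, samples whose winner is the unstable
BL2 subtype are reassigned to their second-highest score, and BL1 is
reported as BL — five stable calls (BL, IM, M, LAR, MSL), no sample left
unassigned.

**Weighted survival** (`jnksig.survweight`). In a case-cohort design every
case is included and non-cases are subsampled within strata; analyses
reweight each subject by the inverse of its stratum's sampling fraction
(generalized Horvitz–Thompson). The package implements the weighted
Kaplan–Meier product-limit estimator and a Newton–Raphson maximiser of the
weighted Breslow partial likelihood with Lin–Wei robust sandwich standard
errors (validated against R `survival::coxph`). The interaction hazard
ratio between biomarker strata is HR_inter = exp(β_interaction) with a
Wald p from the robust SE; families of interaction p values receive
Benjamini–Hochberg q values.

**Synthetic cohorts** (`jnksig.synthio`) provide the ground truth for all
of this: a latent phospho level with a known correlated gene subset,
subtype centroid structure, TIL percentages, proportional-hazards
survival over four nested endpoints with configurable interaction
effects, and stratified 1:3 case-cohort sampling.

## Worked example

```bash
cat > demo_cfg.json <<'EOF'
{
  "simulation": {"n_samples": 200, "n_genes": 800, "n_signal_genes": 15},
  "derivation": {"n_iterations": 200},
  "min_mapped_reads": 10000,
  "endpoints": ["DFS"]
}
EOF
jnksig run --config demo_cfg.json --seed 7 --outdir demo_out
```

prints (abridged):

```
report hash 52696d4ca70add4b51d17e3f30998c707ecb1a0b0b9ba7f92ec68ddd85238505
{
  "n_analyzed": 200,
  "n_cases": 35,
  "n_included_case_cohort": 140,
  "pjnk_group_sizes": {"high": 100, "low": 100},
  "subtype_counts": {"BL": 46, "IM": 36, "LAR": 22, "M": 64, "MSL": 32}
}
```

and writes `demo_out/report.json` plus TSV tables. In this run the derived
15-gene signature tracks the held-out latent phospho level at Pearson
r = 0.918; the weighted 5-year DFS estimates are 0.759 (pJNK-low) vs 0.740
(pJNK-high), and the DFS subtype × pJNK interaction table reads

| subtype | HR_inter | p_inter | q_inter |
|---------|---------:|--------:|--------:|
| BL      | 0.36     | 0.293   | 0.734   |
| IM      | 6.60     | 0.074   | 0.371   |
| M       | 0.60     | 0.497   | 0.747   |
| LAR     | 2.14     | 0.598   | 0.747   |
| MSL     | 0.81     | 0.839   | 0.839   |

HR_inter is the ratio of the subtype's hazard ratio in the pJNK-low
stratum to that in the pJNK-high stratum; q_inter is the BH-adjusted
p value within the endpoint's five-subtype family. (The generator's
default hazard effects include an IM × pJNK interaction, which is why the
IM row stands out even at this small demonstration size.) The report hash
is reproducible: rerunning the same config and seed yields the identical
report byte for byte.

The same stages are available as library calls (`run_full_pipeline`,
`derive_signature`, `score_samples`, `assign_subtype`,
`weighted_cox_fit`, …) and as individual CLI verbs (`simulate`, `derive`,
`score`, `classify`, `survive`).

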