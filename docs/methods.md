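# Methods

## Study design being modelled

The package targets the canonical candidate-gene case-control design: a
panel of biallelic SNPs previously reported to modify disease risk is
genotyped in cases and controls, each SNP is tested for allelic
association, and the per-SNP information is pooled into a weighted
multilocus genetic risk score (GRS) that is then evaluated alongside
clinical covariates. The reference scenario throughout is atrial
fibrillation (AF) in haemodialysed end-stage kidney disease patients:
113 cases (about half with permanent AF), 157 controls, 16 genotyped
SNPs of which 13 survive quality control.

## Per-SNP quality control

Two exclusion rules, applied per SNP in this order:

* **Call rate** — the fraction of samples with a non-missing genotype.
  SNPs strictly below 0.80 are excluded. The boundary case (exactly 80%)
  is retained; the comparison is done in exact rational arithmetic so the
  boundary cannot be crossed by float rounding.
* **Hardy-Weinberg equilibrium (HWE)** — the exact conditional test:
  given the observed allele counts, the probability of `h` heterozygotes
  is proportional to the multinomial count of genotype configurations
  times 2^h, and the P value sums the probabilities of all configurations
  no more probable than the observed one. Implemented with integer
  arithmetic (exact up to the final division) and verified against a
  brute-force enumeration oracle for all genotype totals ≤ 50. SNPs with
  P < 0.05 are excluded; monomorphic SNPs return P = 1 with a flag. A χ²
  variant is provided for cross-checks.

By default HWE is tested **in controls only**, the standard case-control
practice (a true risk variant distorts genotype proportions among cases);
`hwe_stratum="all"` is available. The analysed-SNP count m that survives
QC is the single Bonferroni denominator used everywhere downstream — the
pipeline asserts this consistency on every run.

## Allelic association

Each SNP is summarised as a 2×2 allele-count table (risk/non-risk ×
case/control), the behaviour of PLINK's basic allelic test. Sub-phenotype
contrasts (non-permanent AF, permanent AF) reuse the full control group.
Missing genotypes are dropped per SNP (pairwise deletion), so genotyped
Ns vary across SNPs; this deliberately differs from the GRS's
complete-case rule.

* **Odds ratio**: OR = ad/bc with Woolf's CI
  `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`. Any empty cell triggers
  the Haldane–Anscombe correction (0.5 added to every cell, flagged);
  two empty cells on a diagonal make the OR undefined (flagged, not an
  error). 1.96 is used verbatim rather than the exact normal quantile,
  matching how such tables are conventionally reported.
* **P value**: 1-df Pearson χ² without continuity correction, with an
  optional Fisher-exact fallback when an expected cell is below 5.
  Degenerate margins give P = 1 with a flag.
* **Bonferroni**: `p_corr = min(1, m·p)`. Report tables carry the full
  correction for every row plus a column filled only for nominal
  (p < 0.05) results, the convention used in printed sub-phenotype
  tables.

## Genetic risk score

`GRS = Σᵢ dosageᵢ · ln(ORᵢ)` over the analysed SNPs, with dosage the
count of risk-allele copies (0/1/2) and OR the *published* literature
odds ratio carried by the panel — weights are never re-estimated from
the cohort under analysis. Missing genotypes are handled by
complete-case exclusion: a sample missing any analysed genotype gets no
score and is listed in the exclusion set (at the reference missingness
scale this loses roughly 40 of 270 samples, matching the accounting such
studies report). A renormalised-score variant (rescaling by observed
weight mass) exists but is off by default, since exclusion is the
documented behaviour being reproduced.

Group contrasts (AF, non-permanent AF and permanent AF, each versus
controls) use the two-sample pooled-variance Student t test
(df = n₁ + n₂ − 2); Welch's test is available via a flag. Zero pooled
variance is handled explicitly (t = 0, P = 1 for equal means; flagged
infinite t otherwise).

## Logistic modelling

The disease model is fitted by maximum likelihood (statsmodels `Logit`)
on complete-case rows, with the dropped-row count reported. The default
predictor set mirrors the reference study: age, sex, smoking, BMI,
presence of diuresis, coronary artery disease, myocardial infarction,
myocardial hypertrophy, and the GRS.

* **McFadden pseudo-R²** = 1 − ln(Lm)/ln(L0). L0 is computed in closed
  form (the intercept-only MLE fits the observed case fraction exactly),
  and the implementation is tested against an independent per-sample
  log-likelihood summation.
* **Per-0.1-unit GRS OR** = exp(0.1·β) with CI exp(0.1·(β ± 1.96·se)).
  The GRS enters the model unscaled; only the presentation is rescaled.
* **Classification accuracy** is resubstitution accuracy at threshold
  0.5; a probability exactly at the threshold classifies as a case
  (documented, arbitrary tie-break). No cross-validation is attempted —
  the quantity being reproduced is in-sample.
* **Reduction** is a single backward step keeping terms with Wald
  P < 0.05, refitted on the same rows so nested likelihoods are
  comparable. Under the null each candidate term is falsely retained at
  ~5%, so "exact recovery" of a true predictor set necessarily fails in
  a corresponding fraction of replicates; the test-suite freezes the
  observed behaviour at fixed seeds (all true terms retained in 20/20
  seeds, exact recovery in ≥16/20 with two null candidates).
* **Degenerate fits**: perfect separation and singular designs return a
  non-converged result with NaN coefficients and a diagnostic string —
  never silently huge estimates. Constant predictors are dropped with a
  warning.

## Synthetic cohorts

`simulate_cohort` draws a population in which genotypes are
Binomial(2, RAF) per SNP — HWE by construction, no linkage
disequilibrium (the candidate loci lie in different genes) — covariates
follow simple parametric laws, and disease is Bernoulli with
`logit(P) = β₀ + Σ β_snp·dosage + Σ β_cov·cov`. Normal covariates enter
the linear predictor centred at their mean so the intercept keeps its
interpretation. Case-control ascertainment is by rejection sampling:
draws are accepted into each arm until the requested sizes are filled
(bounded; an unattainable configuration raises). When no intercept is
supplied it is calibrated on a dedicated random stream so the population
case probability matches the target case fraction (default 113/270);
ascertainment leaves the covariate and per-allele log-ORs identifiable,
which is what the recovery checks rely on.

Default scenario parameters (chosen once, at the scale of the cohort
being emulated, and treated as fixed study conditions):

| parameter | default | rationale |
|---|---|---|
| n_case / n_control | 113 / 157 | reference cohort arm sizes |
| SNP RAFs | per-SNP, 0.10–0.88 | plausible European control frequencies for these loci |
| SNP effects | ln(panel OR), ORs 1.07–1.64 | literature-scale AF effect sizes; the panel ORs double as the true simulation effects |
| sex_male | p = 0.55, OR 2.3 | cohort prevalence; effect at the scale of the reported independent association |
| mi | p = 0.30, OR 2.6 | as above |
| ever_smoker | p = 0.45, OR 1.3 | cohort prevalence, modest effect |
| age | Normal(70, 10) yr, β = 0.01/yr | cohort age distribution; weak residual age effect |
| bmi / cad / diuresis / hypertrophy | cohort-scale prevalences, null effects | present so the nine-variable model has realistic null candidates |
| perm_fraction | 0.4865 | observed permanent-AF share among cases |
| missing_rate | 0 (0.0115 in demos) | MCAR; 1−(1−0.0115)¹³ ≈ 14% complete-case loss, the documented exclusion scale |

What the generator does **not** emulate: linkage disequilibrium,
population stratification, genotyping batch effects, informative
(non-MCAR) missingness, covariate correlation (e.g. smoking–sex), or
HWE violations (except through the designed QC-demonstration cohort,
`make_qc_demo_cohort`, which plants one low-call-rate SNP and two gross
HWE violations among 13 SNPs laid out in exact HWE proportions). Passing
tests therefore certify the statistical machinery under the stated
model, not robustness to those real-data complications.

`make_fixture_suite` writes a 20-sample × 5-SNP deterministic fixture
(panel TSV, dosage TSV, VCF with the risk allele on both REF and ALT
sides, phenotypes, truth JSON) used across the test-suite.

## Numerical and design choices

* Dosage files: samples as rows, rsIDs as columns, `NA` for missing; the
  TSV counts risk-allele copies by convention. VCFs use the GT field
  only; phased and unphased calls are equivalent; half-calls (`./1`) are
  conservatively missing. The panel is the sole authority on risk-allele
  orientation.
* Exact-test tie handling is exact: configuration weights are compared
  as integers, so "no more probable than observed" involves no float
  tolerance.
* Call-rate thresholds given as floats are parsed via their decimal
  string (0.8 → 4/5) before the rational comparison.
* Report tables round ORs/CIs and frequencies to 2 decimals and P values
  to 3 significant figures; full precision is kept internally and all
  outputs are byte-deterministic for a fixed config and seed.
* Problem sizes in the verification suite — 20 seeds at n = 1000/1000
  for recovery checks, genotype totals ≤ 50 for the exact-test oracle
  sweep — were chosen to make sampling bands tight enough to be
  meaningful while keeping the whole suite fast to run routinely.

## Known limitations

* Only biallelic SNVs are supported: no indels, multi-allelic sites,
  imputation, liftover or binary PLINK formats.
* No per-sample QC (reference studies excluded samples on wet-lab
  grounds before analysis).
* Association offers the allelic test only — no genotypic, dominant or
  recessive models, and no covariate-adjusted per-SNP tests.
* Multiple-testing correction is Bonferroni only, matching the analysis
  being reproduced.
* Discrimination is resubstitution accuracy; no C-statistic or
  reclassification analysis.
* Real cohorts of this size give the GRS limited power for single-SNP
  claims; the package reproduces the analysis, it does not improve its
  power.
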