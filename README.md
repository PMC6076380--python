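# mirprospect

Prospective blood-miRNA biomarker analysis for matched case–control cohort
studies — built around the design in which COPD patients are profiled at
baseline on a genome-wide miRNA microarray (~2549 mature miRNAs) and followed
for several years, so that patients who later develop cancer (cases, n ≈ 33)
can be compared with matched patients who do not (controls, n ≈ 501).

The package is for bioinformaticians and biostatisticians who need the whole
chain as tested, reusable code:

* **synthetic cohorts** (`mirprospect.synth`) — log-normal intensities with
  replicate probes, planted case/control effects (Cohen's *d* on the log2
  scale, mostly down-regulated in cases), matched covariates, a four-level
  prior-cancer-history grouping, and category sets with a planted positive
  control, so every downstream stage is testable without any data download;
* **normalization** (`mirprospect.normalize`) — background subtraction,
  replicate collapse by per-array median, quantile normalization (ties share
  the mean of their ranks' reference values), log2, and a Shapiro–Wilk
  normality screen on both scales;
* **differential expression** (`mirprospect.diffexp`) — per-miRNA Welch or
  pooled *t*-test **and** Wilcoxon–Mann–Whitney test (exact, tie-aware by
  enumeration for small samples), Benjamini–Hochberg adjustment per test
  family, cohort medians, linear fold change, signed log2 fold change,
  per-miRNA ROC-AUC, dual-test concordance, and volcano-plot export;
* **enrichment** (`mirprospect.enrich`) — the cutoff-free running-sum
  statistic over an AUC-ranked universe (step +(m−l) on category hits, −l on
  misses) with an **exact** p-value computed by a big-integer dynamic program
  over all C(m, l) arrangements, plus the set-based hypergeometric test;
* **confounders** (`mirprospect.confound`) — cohort balance tests (Welch *t*,
  Fisher's exact 2×2, chi-square with seeded permutation fallback),
  genome-wide ANOVA/Pearson covariate screens, and the four-group
  cancer-history analysis with the extreme-group comparison;
* **classification** (`mirprospect.classify`) — small miRNA signatures (2–13
  features) with gradient-boosted trees (LightGBM), per-class weights
  proportional to the class ratio, ANOVA-F feature selection *inside* each
  training fold, and grid search in 5-time repeated 5-fold stratified
  cross-validation;
* **power** (`mirprospect.power`) — noncentral-*t* solver linking group
  sizes, alpha, power and the detectable standardized effect size.

## The statistics at the core

For miRNA *i* with log2 expression x in cases and y in controls, the package
reports t(x, y) with two-tailed p, the rank-sum W with exact two-tailed p
(enumerating all C(n₁+n₂, n₁) mid-rank labelings when samples are small),
BH-adjusted q per family, and AUC = P(X > Y) + ½P(X = Y).

For a category of l miRNAs in a ranked universe of m, the running sum
S_k = Σ_{j≤k} [(m−l)·hit_j − l·miss_j] ends at 0; the statistic is
max_k S_k, and its exact p-value is

    p = #{arrangements with max prefix sum ≥ observed} / C(m, l),

counted by a dynamic program over (position, hits-so-far) in exact integer
arithmetic — no sampling error and no overflow even at m = 2549.

For the design calculation, the detectable Cohen's d solves
power(d) = 1 − β for the two-sided two-sample t-test with noncentrality
δ = d·√(n₁n₂/(n₁+n₂)).

## Worked example

```python
from mirprospect import (SynthConfig, generate, preprocess, CohortSplit,
                         run_diffexp, enrich_cutoff_free, solve_effect_size)

cfg = SynthConfig(n_mirnas=600, n_cases=25, n_controls=100, frac_de=0.05,
                  effect_size_d=1.2, frac_down=0.0, seed=11)
ds = generate(cfg)                      # raw replicate probes + annotation
mat = preprocess(ds.expression)         # background, collapse, quantile, log2
de = run_diffexp(mat, CohortSplit.from_annotation(ds.annotation))

print("significant (BH q_t < 0.05):", int((de.table.q_t < 0.05).sum()),
      "of", len(de.table), "—", len(ds.truth), "planted")
print("t/Wilcoxon p-value concordance: r = %.2f" % de.concordance_r)
print(de.table.nsmallest(3, "q_t")[["fold_change", "q_t", "auc"]].round(4))

enr = enrich_cutoff_free(de.table, ds.categories)   # AUC-descending ranking
print(enr.head(2).round(4))
print("detectable d, 33 vs 33:  %.2f" % solve_effect_size(33, 33, 0.05, 0.95))
print("detectable d, 33 vs 500: %.2f" % solve_effect_size(33, 500, 0.05, 0.95))
```

prints

```
significant (BH q_t < 0.05): 30 of 600 — 30 planted
t/Wilcoxon p-value concordance: r = 0.93
              fold_change  q_t     auc
miRNA
syn-miR-0412       0.4063  0.0  0.8214
syn-miR-0435       0.4253  0.0  0.8350
syn-miR-0571       0.3234  0.0  0.8568
                 l  observed_max  p_exact       q
name
signal_planted  25         14250   0.0000  0.0000
random_05       25          4675   0.0048  0.0263
detectable d, 33 vs 33:  0.90
detectable d, 33 vs 500: 0.65
```

All 30 planted markers are recovered at q < 0.05; the two tests' p-values
agree closely (r = 0.93); the planted category is the top enrichment hit
(here `random_05` also contains a couple of planted members by chance —
categories are drawn from the same universe); fold changes > 1 would mean
down-regulation in cases (here the planted effects are up-regulated, so
FC < 1); and enlarging the control arm from 33 to 500 lowers the detectable
single-miRNA effect size from d ≈ 0.90 to d ≈ 0.65 at alpha 0.05 and power
0.95.

The same pipeline runs from the shell:

```bash
mirprospect simulate --out data/ --seed 11
mirprospect all --out results/ --seed 11
mirprospect power --n1 33 --n2 500 --power 0.95
```

## Documentation

`docs/methods.md` describes the statistical model behind every stage, the
synthetic-data generator's assumptions and limits, the numerical choices
(tie handling, exact-test thresholds, degenerate inputs) and known
limitations.
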