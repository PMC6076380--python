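# Methods

## Study design the package models

A prospective matched cohort: patients with a chronic disease are profiled
once at baseline on a genome-wide miRNA microarray and followed for several
years; the contrast is between patients who later develop cancer (cases) and
matched patients who do not (controls). The canonical dimensions used
throughout the defaults are 2549 miRNAs × 534 samples with 33 cases and 501
controls — a p ≫ n regime with roughly 15:1 class imbalance, which drives
three design choices: Benjamini–Hochberg control of the false discovery rate
across the miRNA family, AUC rather than accuracy as the primary classifier
metric, and class weighting by the inverse class frequencies.

## Synthetic cohorts

The generator (`mirprospect.synth`) draws, per miRNA, a latent log2 baseline
µᵢ ~ U(6, 14) and a log2 SD σᵢ ~ U(0.8, 1.4); sample values are Gaussian on
the log2 scale, i.e. log-normal intensities. Because µ and σ vary across
features, neither the linear nor the log scale is uniformly Gaussian across
the matrix — the situation that motivates running both a parametric and a
rank test downstream. A fraction `frac_de` of miRNAs (default 5%) receives a
case/control mean shift of `effect_size_d`·σᵢ on the log2 scale (default
d = 0.65, the design effect size of the 33-vs-500 cohort); a fraction
`frac_down` of those shifts (default 0.74, matching a cohort in which about
three quarters of nominal markers lose expression in cases) is negative.
Replicate probes (default 3 per miRNA) are independent log2-Gaussian copies
of the latent value (SD 0.1) plus an optional additive background (default
0, i.e. background already excluded). Covariates — age ~ N(67, 7.8²) clipped
to [40, 90], pack-years ~ N(48, 37²) clipped at 0, gender (35% f) and
smoking status (never/past/present at 4.1/72.3/23.6%) — are drawn from one
common distribution in both cohorts, reproducing a matched design whose
balance table comes out non-significant; slopes coupling age or smoking into
a configurable number of non-planted miRNAs are off by default and exist to
exercise the confounder screens. A four-level prior-cancer-history grouping
is sampled conditionally on cohort from `history_group_probs` (default
0.82/0.05/0.10/0.03), so group = 1 + case + 2·history always holds. Each
dataset carries one "signal" category sampling planted miRNAs with
probability 0.8 (topped up at random) plus 10 random categories of the same
size (default 25).

What the generator deliberately does **not** emulate: array spatial
artifacts, batch/scanner effects, intensity-dependent variance, correlated
miRNA co-expression blocks, missing values, and distribution parameters
fitted to any real array (none are published for the motivating cohort).
Passing tests therefore demonstrate correctness of the statistics and
control of error rates under a clean log-normal world, not robustness to
real-array pathology.

## Normalization

Processing states are explicit (`raw → collapsed → normalized → log2`) and
checked by every operation. Background subtraction clamps at a positive
floor (default 1 intensity unit) so log2 stays defined without imputation;
with background 0 it is an exact identity. Replicates collapse to the
per-array median. Quantile normalization maps each column onto the vector of
per-rank means of the column-sorted matrix; within a column, tied values
share the mean of the reference values at their tied ranks — the
deterministic convention. Consequences pinned by tests: the procedure is
idempotent and the post-normalization column multisets are identical exactly
when columns are tie-free; tie blocks perturb both properties slightly. The
default order is quantile normalization on the linear scale followed by
log2; `log_before_normalize` flips the order, since both appear in
microarray practice and the switch keeps the choice auditable. The
Shapiro–Wilk screen reports per-miRNA p-values on both scales (constant rows
are flagged not-applicable and excluded from the summary fractions).

## Differential expression

The t-test defaults to Welch's form — with 33 vs 501 samples the pooled
variance is dominated by the large arm, and Welch is the safer default under
that imbalance — with the pooled form available by flag (and used where the
F = t² identity with one-way ANOVA is wanted). Degenerate rows are resolved
deterministically: two identical constant groups give (t, p) = (0, 1), two
unequal constant groups give (±∞, 0) with a warning.

The Wilcoxon–Mann–Whitney p-value is exact by full enumeration of the
mid-rank permutation distribution when n₁+n₂ ≤ 12 (the two-tailed p is
P(|S − µ| ≥ |observed − µ|) with µ = n₁(n+1)/2, valid under ties); for
larger tie-free samples the exact distribution is taken from scipy; large
tied samples use either a seeded Monte-Carlo permutation p (with the +1
correction that keeps it a valid permutation p) or the normal approximation
with tie correction, which is also the genome-wide default at cohort scale.

Benjamini–Hochberg is applied separately to the t family and the Wilcoxon
family across all miRNAs of one comparison. Fold change is reported twice to
avoid orientation ambiguity: the linear ratio of cohort-1 to cohort-2
medians (so down-regulation in cases gives FC > 1) and the signed log2
difference cohort2 − cohort1 used by the volcano export. AUC uses the
Mann–Whitney identity with ties counting one half. Dual-test concordance is
the Pearson correlation of the two raw p-value vectors (a −log10 variant is
available by flag; the raw-p convention is the default).

## Enrichment

The ranked universe defaults to AUC descending — the most over-expressed
miRNA in cases first — with a signed −log10 p alternative. The running sum
steps +(m−l) on hits and −l on misses, hence always terminates at 0, and the
statistic is the maximum prefix sum. Its p-value is exact: a dynamic program
over (position, hits-so-far) counts, in Python big-integer arithmetic, the
arrangements whose every prefix stays below the observed maximum (the prefix
sum after i positions with h hits is h·m − i·l, so feasibility is a lattice
condition); the complement over C(m, l) is the p-value. Runtime is O(m·l)
big-integer additions — about 20 ms at m = 2549, l = 50. The tail convention
is ≥ (the observed arrangement counts itself), which keeps the p-value
strictly positive and valid as a permutation p; strict > is selectable. The
statistic is one-sided toward the top of the ranking; depletion is tested by
reversing the ranking. Categories are intersected with the measured universe
first (absent members are logged), and degenerate categories (l = 0 or
l = m) are skipped with a warning. The set-based test is the upper-tail
hypergeometric p of the overlap between the BH-significant set and each
category against the universe; both tests report raw p and BH q across
categories.

## Confounder screens and history groups

Categorical covariates are screened by per-miRNA one-way ANOVA (levels with
fewer than 2 samples are dropped with a warning), continuous covariates by
per-miRNA Pearson correlation with two-tailed p from the t distribution on
n−2 degrees of freedom; missing covariate values are excluded
pairwise-complete. Cohort balance uses Welch t-tests for age and pack-years,
Fisher's exact 2×2 for gender, and a chi-square contingency test for the
three smoking levels with a seeded label-permutation fallback whenever an
expected cell is below 5 (no closed-form exact r×c test is assumed). The
four-group history analysis runs the per-miRNA 4-level ANOVA plus a full
differential-expression comparison of the extreme groups (no history & no
cancer vs history & cancer); the ANOVA is skipped if a group is empty while
the extreme comparison is still attempted when groups 1 and 4 have ≥ 2
samples each.

## Classification

Gradient-boosted trees are taken by contract — an additive tree ensemble
with logistic loss, tunable leaves and trees, and per-class sample weights —
with LightGBM as the implementation. Per-class weights are N/(2n_c), i.e.
proportional to the class ratio. Feature selection (top-k by between-class
ANOVA F, ties broken lexicographically) is re-run inside every training fold
of a repeated stratified k-fold; selecting on the full data first is a
leakage that demonstrably inflates null AUC, and a regression test keeps the
two protocols apart. The grid defaults to signature sizes 2–13, leaves
{7, 15, 31} and trees {50, 100, 200}; the winner by mean cross-validated AUC
(parsimony tie-break: fewer features, then smaller model) is refit on the
full data to name the reported signature. Accuracy and balanced accuracy are
reported alongside AUC, but model selection uses AUC because accuracy
saturates under 15:1 imbalance. All folding and fitting is single-threaded
and seeded, so repeated runs are bit-identical. The end-to-end pipeline
defaults to a lighter grid (k ∈ {2, 3, 5, 8, 13}, 31 leaves, 100 trees) so a
full synthetic run finishes in well under a minute; the full grid remains
the `ClassifierConfig` default for dedicated analyses.

## Power

The solver uses the noncentral-t power function of the two-sided two-sample
t-test (noncentrality δ = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2), root-finding d
by Brent's method to power error < 1e-8. The normal-approximation engine
(d = (z₁₋α/₂ + z_power)·√(1/n₁+1/n₂), both tails) is a cross-check; it sits
slightly below the noncentral-t answer (it ignores the estimated-variance
penalty) with a gap of about 0.014 at n = 30 per group that vanishes as n
grows. At the design point: 33 vs 33 at alpha 0.05 and power 0.95 gives
d = 0.901; 33 vs 500 gives d = 0.649.

## Numerical and reproducibility choices

* One global pipeline seed; each stochastic stage derives a stable sub-seed
  (< 2³¹) from the seed and the stage name via `numpy.random.SeedSequence`.
* Exact arithmetic wherever a p-value is called exact: big integers for the
  enrichment DP, rational division via `fractions.Fraction` before the final
  float.
* BH is the standard step-up with a cumulative minimum from the largest
  rank; it matches `statsmodels.multipletests(method="fdr_bh")` to machine
  precision (tested).
* All writers emit newline-terminated, full-precision TSV/CSV/GMT; readers
  parse floats in round-trip mode, so write → read → write is byte-identical.
* The run manifest records package and library versions, the seed and a
  SHA-256 of the config (excluding the output directory), and no timestamps,
  so same-seed runs are hash-identical.

## Test problem sizes

The statistical guarantees are exercised at the dimensions the analysis
targets wherever that is cheap (null FDR control and planted-marker recovery
run at 2549 × 534 over 20 and 1 seeds respectively; classifier sanity runs
at full dimensions with a single grid point) and at reduced dimensions for
the heavier protocol tests (weighting benefit across 20 seeds at 60 × 156),
sizes chosen so the whole suite runs in a couple of minutes on one CPU.
Enrichment exactness is verified exhaustively for every universe size up to
12, and calibration at m = 200, l = 15 over 500 random rankings against a
99% DKW band.

## Known limitations

* The generator's independence across miRNAs understates the correlation of
  real co-regulated miRNAs, which makes BH behave closer to its nominal
  bound than it may on real arrays.
* The exact Wilcoxon enumeration is limited to small totals by design;
  large tied samples fall back to Monte Carlo or the tie-corrected normal
  approximation rather than a shift-algorithm exact distribution.
* The permutation fallback for sparse contingency tables is Monte Carlo, not
  a full network-algorithm exact test.
* No batch-effect modeling or correction: quantile normalization is the only
  between-array harmonization, matching the analysis being reproduced.
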