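"""Clinical covariate screens and the four-group cancer-history analysis.

The cohort design matches cases and controls on age, gender and smoking
history; these screens verify the matching (cohort balance tests), quantify
residual covariate-expression association genome-wide (one-way ANOVA for
categorical covariates, Pearson correlation for continuous ones, each with a
BH-adjusted family), and stratify the case/control contrast by prior cancer
history: group 1 = no history & no cancer, 2 = no history & developed
cancer, 3 = history & no cancer, 4 = history & developed cancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import CohortSplit, DiffExpResult, benjamini_hochberg, run_diffexp
from .exceptions import ConfigurationError, StructuralError
from .matrix import ExpressionMatrix

__all__ = [
    "validate_annotation",
    "anova_screen",
    "correlation_screen",
    "history_group_analysis",
    "HistoryGroupResult",
    "cohort_balance_tests",
]

REQUIRED_COLUMNS = ("sample_id", "cohort", "history", "group", "age", "gender", "smoking", "packyears")
GENDERS = ("f", "m")
SMOKING_LEVELS = ("never", "past", "present")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation table's schema and internal consistency.

    The four history groups must be the cross of history (0/1) and cohort
    (control/case): groups 1/2 have history 0, groups 3/4 have history 1;
    groups 1/3 are controls, 2/4 are cases.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in ann.columns]
    if missing:
        raise StructuralError(f"annotation is missing columns: {missing}")
    if ann["sample_id"].duplicated().any():
        raise StructuralError("duplicate sample_id in annotation")
    if not set(ann["cohort"]) <= {"control", "case"}:
        raise StructuralError("cohort labels must be 'control' or 'case'")
    if not set(ann["gender"].dropna()) <= set(GENDERS):
        raise StructuralError(f"gender must be one of {GENDERS}")
    if not set(ann["smoking"].dropna()) <= set(SMOKING_LEVELS):
        raise StructuralError(f"smoking must be one of {SMOKING_LEVELS}")
    expected_group = 1 + (ann["cohort"] == "case").astype(int) + 2 * ann["history"].astype(int)
    if not (ann["group"].astype(int) == expected_group).all():
        bad = ann.loc[ann["group"].astype(int) != expected_group, "sample_id"].tolist()
        raise StructuralError(f"group inconsistent with (history, cohort) for: {bad[:5]}")
    return ann


def _aligned_covariate(mat: ExpressionMatrix, series: pd.Series) -> pd.Series:
    """Align a per-sample covariate with the matrix columns."""
    series = series.copy()
    if not series.index.equals(pd.Index(mat.values.columns)):
        series = series.reindex(mat.values.columns)
    return series


def anova_screen(
    mat: ExpressionMatrix, factor: pd.Series, min_level_size: int = 2
) -> pd.DataFrame:
    """One-way ANOVA of each miRNA across the levels of a categorical covariate.

    Samples with a missing factor value are excluded; levels with fewer than
    ``min_level_size`` samples are dropped with a warning. Returns a table
    with columns F, p, q (BH across miRNAs).
    """
    mat.require_state("log2")
    factor = _aligned_covariate(mat, factor)
    keep = factor.notna()
    counts = factor[keep].value_counts()
    small = counts[counts < min_level_size].index.tolist()
    if small:
        warnings.warn(f"dropping factor levels with <{min_level_size} samples: {small}", stacklevel=2)
        keep &= ~factor.isin(small)
    levels = factor[keep].unique()
    if len(levels) < 2:
        raise ConfigurationError("factor needs at least 2 usable levels")
    arr = mat.values.to_numpy(float)
    groups = [arr[:, (factor == lev).to_numpy() & keep.to_numpy()] for lev in levels]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*groups, axis=1)
    f_stat = np.asarray(f_stat, float)
    p = np.asarray(p, float)
    degenerate = ~np.isfinite(p)
    f_stat[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame(
        {"F": f_stat, "p": p, "q": benjamini_hochberg(p)}, index=mat.values.index
    )


def correlation_screen(mat: ExpressionMatrix, covariate: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each miRNA with a continuous covariate.

    Missing covariate values are excluded pairwise-complete. Returns a table
    with columns r, p, q.
    """
    mat.require_state("log2")
    covariate = _aligned_covariate(mat, covariate).astype(float)
    keep = covariate.notna().to_numpy()
    x = covariate.to_numpy(float)[keep]
    n = x.size
    if n < 3:
        raise ConfigurationError("need at least 3 samples with a covariate value")
    if np.ptp(x) == 0:
        raise ConfigurationError("covariate is constant")
    y = mat.values.to_numpy(float)[:, keep]
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc**2).sum(axis=1) * (xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame({"r": r, "p": p, "q": benjamini_hochberg(p)}, index=mat.values.index)


@dataclass
class HistoryGroupResult:
    """Four-group ANOVA table plus the extreme-group (1 vs 4) comparison."""

    anova: pd.DataFrame | None
    extreme: DiffExpResult | None


def history_group_analysis(
    mat: ExpressionMatrix, ann: pd.DataFrame, welch: bool = True
) -> HistoryGroupResult:
    """Per-miRNA 4-group ANOVA and a full diffexp between groups 1 and 4.

    The ANOVA is skipped (with a warning) when any group is empty; the
    extreme-group comparison is still attempted whenever groups 1 and 4 both
    have at least 2 samples.
    """
    validate_annotation(ann)
    group = ann.set_index("sample_id")["group"].astype(int)
    group = group.reindex(mat.values.columns)
    sizes = group.value_counts().reindex([1, 2, 3, 4], fill_value=0)
    anova_table = None
    if (sizes > 0).all():
        anova_table = anova_screen(mat, group, min_level_size=2)
    else:
        warnings.warn(f"empty history group(s) {sizes[sizes == 0].index.tolist()}; ANOVA skipped", stacklevel=2)
    extreme = None
    if sizes[1] >= 2 and sizes[4] >= 2:
        split = CohortSplit(
            cohort1_ids=group.index[group == 1].tolist(),
            cohort2_ids=group.index[group == 4].tolist(),
        )
        extreme = run_diffexp(mat, split, welch=welch)
    return HistoryGroupResult(anova=anova_table, extreme=extreme)


def _chi2_or_permutation(table: np.ndarray, seed: int, n_perm: int = 10_000):
    """Chi-square contingency test with a seeded permutation fallback when any
    expected cell count is below 5 (the usual validity rule of thumb)."""
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected >= 5).all():
        return "chi2", float(chi2), float(p)
    # permutation of the row labels, conditioning on the margins
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        c2 = stats.chi2_contingency(t, correction=False)[0]
        if c2 >= chi2 - 1e-12:
            hits += 1
    return "chi2_permutation", float(chi2), hits / (n_perm + 1)


def cohort_balance_tests(ann: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Case/control comparability of age, pack-years, gender and smoking.

    Age and pack-years: Welch t-test. Gender: Fisher's exact 2x2. Smoking:
    chi-square contingency test with a seeded permutation fallback for sparse
    tables. Returns one row per covariate with the test name, statistic and p.
    """
    validate_annotation(ann)
    is_case = (ann["cohort"] == "case").to_numpy()
    if is_case.all() or (~is_case).all():
        raise ConfigurationError("both cohorts must be non-empty")
    rows = []
    for col in ("age", "packyears"):
        x = ann.loc[~is_case, col].dropna().to_numpy(float)
        y = ann.loc[is_case, col].dropna().to_numpy(float)
        t, p = stats.ttest_ind(y, x, equal_var=False)
        rows.append({"covariate": col, "test": "welch_t", "statistic": float(t), "p": float(p)})
    gender_tab = pd.crosstab(ann["cohort"], ann["gender"]).reindex(
        index=["control", "case"], columns=list(GENDERS), fill_value=0
    )
    odds, p = stats.fisher_exact(gender_tab.to_numpy())
    rows.append({"covariate": "gender", "test": "fisher_exact", "statistic": float(odds), "p": float(p)})
    smoke_tab = pd.crosstab(ann["cohort"], ann["smoking"]).reindex(
        index=["control", "case"], columns=list(SMOKING_LEVELS), fill_value=0
    )
    used = smoke_tab.loc[:, smoke_tab.sum(axis=0) > 0].to_numpy()
    test, stat, p = _chi2_or_permutation(used, seed=seed)
    rows.append({"covariate": "smoking", "test": test, "statistic": stat, "p": float(p)})
    return pd.DataFrame(rows).set_index("covariate")
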