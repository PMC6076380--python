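"""Two-cohort genome-wide differential expression.

Each miRNA is tested twice — an unpaired two-tailed t-test (Welch by
default, pooled optionally) and a rank-based two-tailed
Wilcoxon–Mann–Whitney test, with an exact tie-aware variant for small
samples — and the two raw p-value families are each adjusted with
Benjamini–Hochberg. Per-miRNA effect summaries are the cohort medians, the
linear fold change, the signed log2 fold change, and the ROC-AUC
(probability that a random case value exceeds a random control value, ties
counting one half). A concordance report (Pearson correlation between the
two tests' raw p-value vectors) quantifies parametric/non-parametric
agreement.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, StructuralError
from .matrix import ExpressionMatrix

__all__ = [
    "CohortSplit",
    "DiffExpResult",
    "t_test_two_tailed",
    "wilcoxon_exact",
    "benjamini_hochberg",
    "roc_auc",
    "run_diffexp",
]


@dataclass
class CohortSplit:
    """Sample ids of cohort 1 (no cancer) and cohort 2 (developed cancer)."""

    cohort1_ids: list[str]
    cohort2_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.cohort1_ids) & set(self.cohort2_ids)
        if overlap:
            raise StructuralError(f"cohorts overlap: {sorted(overlap)[:5]}")
        if self.n1 < 2 or self.n2 < 2:
            raise ConfigurationError("each cohort needs at least 2 samples")

    @property
    def n1(self) -> int:
        return len(self.cohort1_ids)

    @property
    def n2(self) -> int:
        return len(self.cohort2_ids)

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame) -> "CohortSplit":
        """Build from an annotation table with `sample_id` and `cohort` columns."""
        c1 = annotation.loc[annotation["cohort"] == "control", "sample_id"].tolist()
        c2 = annotation.loc[annotation["cohort"] == "case", "sample_id"].tolist()
        return cls(c1, c2)


def t_test_two_tailed(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed two-sample t-test.

    Welch's form by default; set ``equal_var`` for the pooled-variance form.
    Degenerate inputs are resolved deterministically: two identical constant
    groups give (0, 1); two unequal constant groups give (+/-inf, 0) with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("each group needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        warnings.warn("both groups constant but unequal; t-test degenerate", stacklevel=2)
        return math.copysign(math.inf, x[0] - y[0]), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def _ranksum_two_tailed_p(all_ranks: np.ndarray, n1: int, observed: float) -> float:
    """Exact two-tailed p by full enumeration of C(n, n1) labelings of mid-ranks."""
    n = all_ranks.size
    mu = n1 * (n + 1) / 2.0  # mean of mid-ranks is (n+1)/2 even with ties
    dev = abs(observed - mu)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        s = all_ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_exact(
    x,
    y,
    method: str = "auto",
    exact_threshold: int = 12,
    mc_permutations: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-tailed Wilcoxon–Mann–Whitney test; returns (rank-sum of ``x``, p).

    ``method``:

    * ``"auto"`` — exact for small samples (full enumeration of the mid-rank
      permutation distribution when ``n1+n2 <= exact_threshold``, or scipy's
      exact distribution when there are no ties and the total is moderate),
      otherwise the normal approximation with tie correction.
    * ``"exact"`` — force an exact/tie-aware answer: enumeration for small
      samples, scipy's exact distribution when tie-free, Monte Carlo
      permutation (seeded) when large *and* tied.
    * ``"normal"`` — normal approximation with tie correction.
    * ``"mc"`` — seeded Monte Carlo permutation of labels.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("each group needs at least 1 value")
    n1, n = x.size, x.size + y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    if method not in ("auto", "exact", "normal", "mc"):
        raise ConfigurationError(f"unknown wilcoxon method {method!r}")

    if method == "mc":
        return w, _ranksum_mc_p(ranks, n1, w, mc_permutations, seed)
    if method == "normal" or (method == "auto" and n > exact_threshold):
        if np.ptp(pooled) == 0:
            return w, 1.0
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return w, float(res.pvalue)
    # exact paths
    if n <= exact_threshold or (has_ties and n <= 16):
        return w, _ranksum_two_tailed_p(ranks, n1, w)
    if not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return w, float(res.pvalue)
    return w, _ranksum_mc_p(ranks, n1, w, mc_permutations, seed)


def _ranksum_mc_p(ranks: np.ndarray, n1: int, observed: float, n_perm: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    n = ranks.size
    mu = n1 * (n + 1) / 2.0
    dev = abs(observed - mu)
    hits = 1  # include the observed labeling for a valid permutation p
    for _ in range(n_perm):
        s = rng.permutation(ranks)[:n1].sum()
        if abs(s - mu) >= dev - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    ``adjusted_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values,
    capped at 1, mapped back to the input order.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ConfigurationError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    np.minimum(adj, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out


def roc_auc(cases, controls) -> float:
    """P(random case value > random control value) + 0.5 * P(equal)."""
    cases = np.asarray(cases, float)
    controls = np.asarray(controls, float)
    if cases.size == 0 or controls.size == 0:
        raise ConfigurationError("each group needs at least 1 value")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[: cases.size].sum() - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


@dataclass
class DiffExpResult:
    """Per-miRNA differential expression table plus the dual-test concordance.

    ``table`` columns: median_cohort1, median_cohort2 (log2), fold_change
    (linear cohort1/cohort2, so down-regulation in cases gives FC > 1),
    log2_fc (cohort2 - cohort1), t_stat, p_t, q_t, w_stat, p_w, q_w, auc.
    """

    table: pd.DataFrame
    concordance_r: float
    concordance_p: float
    n1: int
    n2: int
    welch: bool = True
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    def significant(self, test: str = "t", alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        col = {"t": "q_t", "wilcoxon": "q_w"}[test]
        return self.table[self.table[col] < alpha]

    def volcano_table(self, test: str = "t") -> pd.DataFrame:
        """Data behind the volcano plot: log2 FC vs -log10 raw p, with the
        up/down/ns coloring classes and the BH significance line."""
        pcol, qcol = ("p_t", "q_t") if test == "t" else ("p_w", "q_w")
        t = self.table
        status = np.where(
            t[pcol] >= 0.05, "ns", np.where(t["log2_fc"] > 0, "up_in_cohort2", "up_in_cohort1")
        )
        out = pd.DataFrame(
            {
                "log2_fc": t["log2_fc"],
                "neg_log10_p": -np.log10(np.maximum(t[pcol], np.finfo(float).tiny)),
                "p": t[pcol],
                "q": t[qcol],
                "status": status,
            },
            index=t.index,
        )
        sig = t.loc[t[qcol] < self.alpha, pcol]
        out.attrs["bh_line_neg_log10_p"] = float(-np.log10(sig.max())) if len(sig) else np.nan
        return out

    def plot_volcano(self, test: str = "t", ax=None):
        """Volcano plot (matplotlib Axes); colors follow the cohort convention."""
        import matplotlib.pyplot as plt

        data = self.volcano_table(test=test)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        palette = {"ns": "0.6", "up_in_cohort1": "tab:green", "up_in_cohort2": "tab:red"}
        for status, sub in data.groupby("status"):
            ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=6, c=palette[status], label=status)
        line = data.attrs.get("bh_line_neg_log10_p", np.nan)
        if np.isfinite(line):
            ax.axhline(line, color="tab:blue", lw=1)
        ax.set_xlabel("log2 fold change (cohort2 - cohort1)")
        ax.set_ylabel("-log10 raw p")
        ax.legend(fontsize=7)
        return ax


def run_diffexp(
    mat: ExpressionMatrix,
    split: CohortSplit,
    welch: bool = True,
    wilcoxon_method: str = "auto",
    exact_threshold: int = 12,
    alpha: float = 0.05,
    concordance_on_log: bool = False,
) -> DiffExpResult:
    """Genome-wide two-cohort differential expression on a log2 matrix."""
    mat.require_state("log2")
    unknown = [s for s in split.cohort1_ids + split.cohort2_ids if s not in mat.values.columns]
    if unknown:
        raise StructuralError(f"sample ids not in the expression matrix: {unknown[:5]}")

    x1 = mat.values.loc[:, split.cohort1_ids].to_numpy(float)  # controls
    x2 = mat.values.loc[:, split.cohort2_ids].to_numpy(float)  # cases
    n1, n2 = split.n1, split.n2
    n_features = x1.shape[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_t = stats.ttest_ind(x2, x1, axis=1, equal_var=not welch)
    t_stat = np.asarray(t_stat, float)
    p_t = np.asarray(p_t, float)
    # degenerate rows: both groups constant
    both_const = (np.ptp(x1, axis=1) == 0) & (np.ptp(x2, axis=1) == 0)
    if both_const.any():
        equal = both_const & (x1[:, 0] == x2[:, 0])
        t_stat[equal], p_t[equal] = 0.0, 1.0
        diff = both_const & ~equal
        t_stat[diff] = np.sign(x2[diff, 0] - x1[diff, 0]) * np.inf
        p_t[diff] = 0.0

    total_n = n1 + n2
    if total_n <= exact_threshold and wilcoxon_method in ("auto", "exact"):
        w_stat = np.empty(n_features)
        p_w = np.empty(n_features)
        for i in range(n_features):
            w_stat[i], p_w[i] = wilcoxon_exact(
                x2[i], x1[i], method="exact", exact_threshold=exact_threshold
            )
        u = w_stat - n2 * (n2 + 1) / 2.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(x2, x1, axis=1, alternative="two-sided", method="asymptotic")
        u = np.asarray(res.statistic, float)
        p_w = np.asarray(res.pvalue, float)
        w_stat = u + n2 * (n2 + 1) / 2.0
        const_rows = np.ptp(np.concatenate([x1, x2], axis=1), axis=1) == 0
        p_w[const_rows] = 1.0
        u[const_rows] = n1 * n2 / 2.0
    auc = u / (n1 * n2)

    med1 = np.median(x1, axis=1)
    med2 = np.median(x2, axis=1)
    log2_fc = med2 - med1
    fold_change = np.exp2(med1 - med2)  # cohort1 / cohort2 on the linear scale

    table = pd.DataFrame(
        {
            "median_cohort1": med1,
            "median_cohort2": med2,
            "fold_change": fold_change,
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p_t": p_t,
            "q_t": benjamini_hochberg(np.clip(p_t, 0, 1)),
            "w_stat": w_stat,
            "p_w": p_w,
            "q_w": benjamini_hochberg(np.clip(p_w, 0, 1)),
            "auc": auc,
        },
        index=mat.values.index,
    )

    pt, pw = table["p_t"].to_numpy(), table["p_w"].to_numpy()
    if concordance_on_log:
        tiny = np.finfo(float).tiny
        pt, pw = -np.log10(np.maximum(pt, tiny)), -np.log10(np.maximum(pw, tiny))
    ok = np.isfinite(pt) & np.isfinite(pw)
    if ok.sum() >= 3 and np.ptp(pt[ok]) > 0 and np.ptp(pw[ok]) > 0:
        r, rp = stats.pearsonr(pt[ok], pw[ok])
    else:
        r, rp = np.nan, np.nan

    return DiffExpResult(
        table=table,
        concordance_r=float(r),
        concordance_p=float(rp),
        n1=n1,
        n2=n2,
        welch=welch,
        alpha=alpha,
    )
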