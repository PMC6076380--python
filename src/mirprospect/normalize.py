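"""Preprocessing of raw probe intensities into the log2 quantile-normalized matrix.

The chain mirrors standard miRNA microarray practice: subtract background,
collapse replicate probes of one miRNA to their median per array, quantile
normalize across arrays so every sample shares one intensity distribution,
then move to log2. A Shapiro-Wilk screen reports how many miRNAs look
Gaussian on either scale, which motivates running both parametric and
rank-based tests downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError, StructuralError
from .matrix import ExpressionMatrix

__all__ = [
    "subtract_background",
    "collapse_replicates",
    "quantile_normalize",
    "log2_transform",
    "preprocess",
    "normality_screen",
    "NormalityReport",
]


def subtract_background(
    mat: ExpressionMatrix,
    background: float | np.ndarray | pd.Series = 0.0,
    floor: float = 1.0,
) -> ExpressionMatrix:
    """Subtract a scalar or per-sample background, clamping at ``floor``.

    ``floor`` must be positive so that a later log2 stays defined without
    imputation.
    """
    mat.require_state("raw")
    if floor <= 0:
        raise ConfigurationError("floor must be positive (log2 must stay defined)")
    if np.isscalar(background):
        bg = np.full(mat.shape[1], float(background))
    else:
        bg = pd.Series(background).reindex(mat.values.columns).to_numpy(float)
        if np.isnan(bg).any():
            raise ConfigurationError("per-sample background is missing some sample ids")
    if not np.all(np.isfinite(bg)) or (bg < 0).any():
        raise ConfigurationError("background must be finite and nonnegative")
    out = mat.values.to_numpy(float) - bg[None, :]
    np.maximum(out, floor, out=out)
    if np.all(bg == 0):
        out = mat.values.to_numpy(float)  # exact identity, no clamping
    return mat.with_values(
        pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns), "raw"
    )


def collapse_replicates(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate probes to one row per miRNA: per-sample median."""
    mat.require_state("raw")
    if mat.probe_group is None:
        raise StructuralError("collapse_replicates requires a probe_group map on the raw matrix")
    if mat.probe_group.isna().any():
        bad = mat.probe_group.index[mat.probe_group.isna()].tolist()
        raise StructuralError(f"probes without a probe_group label: {bad[:5]}")
    grouped = mat.values.groupby(mat.probe_group, sort=True).median()
    grouped.index.name = mat.values.index.name
    return ExpressionMatrix(values=grouped, state="collapsed")


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank mean distribution.

    Within each column, tied values share the mean of the reference values at
    their tied ranks (the usual deterministic convention).
    """
    mat.require_state("collapsed", "log2")
    arr = mat.values.to_numpy(float)
    n, p = arr.shape
    if p < 2:
        raise ConfigurationError("quantile normalization needs at least 2 samples")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(p):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        new_run = np.empty(n, dtype=bool)
        new_run[0] = True
        np.not_equal(sorted_col[1:], sorted_col[:-1], out=new_run[1:])
        run_id = np.cumsum(new_run) - 1
        sums = np.bincount(run_id, weights=ref)
        counts = np.bincount(run_id)
        out[order, j] = (sums / counts)[run_id]
    state = "log2" if mat.state == "log2" else "normalized"
    return mat.with_values(
        pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns), state
    )


def log2_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; values must be strictly positive."""
    mat.require_state("normalized", "collapsed")
    arr = mat.values.to_numpy(float)
    if (arr <= 0).any() or not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~(arr > 0) | ~np.isfinite(arr))[0]
        raise DataError(
            f"non-positive or non-finite value at row {mat.values.index[i]!r}, "
            f"sample {mat.values.columns[j]!r}: {arr[i, j]}"
        )
    return mat.with_values(
        pd.DataFrame(np.log2(arr), index=mat.values.index, columns=mat.values.columns), "log2"
    )


def preprocess(
    mat: ExpressionMatrix,
    background: float | np.ndarray | pd.Series = 0.0,
    floor: float = 1.0,
    log_before_normalize: bool = False,
) -> ExpressionMatrix:
    """Full chain raw -> log2.

    By default the matrix is quantile normalized on the linear scale and then
    log2-transformed; ``log_before_normalize`` flips the order (both orders
    occur in microarray practice and the switch keeps the choice auditable).
    """
    out = subtract_background(mat, background=background, floor=floor)
    out = collapse_replicates(out) if out.probe_group is not None else ExpressionMatrix(
        out.values, "collapsed"
    )
    if log_before_normalize:
        out = log2_transform(out)
        out = quantile_normalize(out)
    else:
        out = quantile_normalize(out)
        out = log2_transform(out)
    return out


@dataclass
class NormalityReport:
    """Per-miRNA Shapiro-Wilk p-values on the linear and log2 scales.

    ``table`` columns: ``p_linear``, ``p_log2`` (NaN for constant rows,
    which are excluded from the summary fractions), ``usable``.
    """

    table: pd.DataFrame
    alpha: float
    frac_reject_linear: float
    frac_reject_log2: float


def normality_screen(mat: ExpressionMatrix, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk test per miRNA on linear and log2 intensities."""
    mat.require_state("normalized", "collapsed", "log2")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if mat.shape[1] < 3:
        raise ConfigurationError("normality screen needs at least 3 samples")
    arr = mat.values.to_numpy(float)
    if mat.state == "log2":
        log_arr = arr
        lin_arr = np.exp2(arr)
    else:
        lin_arr = arr
        log_arr = np.log2(np.maximum(arr, np.finfo(float).tiny))
    p_lin = np.full(arr.shape[0], np.nan)
    p_log = np.full(arr.shape[0], np.nan)
    usable = np.ptp(arr, axis=1) > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000 / near-constant rows
        for i in np.flatnonzero(usable):
            p_lin[i] = stats.shapiro(lin_arr[i]).pvalue
            p_log[i] = stats.shapiro(log_arr[i]).pvalue
    table = pd.DataFrame(
        {"p_linear": p_lin, "p_log2": p_log, "usable": usable}, index=mat.values.index
    )
    n_usable = int(usable.sum())
    return NormalityReport(
        table=table,
        alpha=alpha,
        frac_reject_linear=float((p_lin[usable] < alpha).sum() / n_usable) if n_usable else np.nan,
        frac_reject_log2=float((p_log[usable] < alpha).sum() / n_usable) if n_usable else np.nan,
    )
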