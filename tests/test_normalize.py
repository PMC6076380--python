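"""Preprocessing chain: background, replicate collapse, quantile normalization, log2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from mirprospect.exceptions import ConfigurationError, DataError, StructuralError
from mirprospect.matrix import ExpressionMatrix
from mirprospect.normalize import (
    collapse_replicates,
    log2_transform,
    normality_screen,
    quantile_normalize,
    subtract_background,
)


def _raw(arr, groups=None):
    arr = np.asarray(arr, float)
    idx = [f"p{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    pg = pd.Series(groups, index=idx) if groups is not None else None
    return ExpressionMatrix(pd.DataFrame(arr, index=idx, columns=cols), "raw", probe_group=pg)


class TestBackground:
    def test_scalar_subtraction_and_floor(self):
        mat = _raw([[100.0, 5.0]])
        out = subtract_background(mat, background=20.0, floor=1.0)
        assert out.values.iloc[0].tolist() == [80.0, 1.0]

    def test_zero_background_is_identity(self):
        mat = _raw([[0.5, 100.0]])
        out = subtract_background(mat, background=0.0)
        assert out.values.equals(mat.values)

    def test_per_sample_vector(self):
        mat = _raw([[100.0, 100.0]])
        out = subtract_background(mat, background=pd.Series({"s0": 10.0, "s1": 30.0}))
        assert out.values.iloc[0].tolist() == [90.0, 70.0]

    def test_negative_background_rejected(self):
        with pytest.raises(ConfigurationError):
            subtract_background(_raw([[1.0, 2.0]]), background=-1.0)


class TestCollapse:
    def test_median_of_replicates(self):
        mat = _raw([[2.0, 2.0], [4.0, 4.0], [6.0, 6.0], [2.0, 2.0], [4.0, 4.0]],
                   groups=["a", "a", "a", "b", "b"])
        out = collapse_replicates(mat)
        assert out.state == "collapsed"
        assert out.values.loc["a"].tolist() == [4.0, 4.0]  # odd count
        assert out.values.loc["b"].tolist() == [3.0, 3.0]  # even count: mean of middle pair
    def test_single_replicate_unchanged(self):
        mat = _raw([[5.0, 7.0]], groups=["a"])
        assert collapse_replicates(mat).values.loc["a"].tolist() == [5.0, 7.0]

    def test_missing_probe_group_rejected(self):
        with pytest.raises(StructuralError):
            collapse_replicates(_raw([[1.0, 2.0]]))

    def test_commutes_with_column_subsetting(self):
        rng = np.random.default_rng(0)
        mat = _raw(rng.uniform(1, 100, (9, 4)), groups=list("aaabbbccc"))
        subset_then_collapse = collapse_replicates(mat.subset_samples(["s0", "s2"]))
        collapse_then_subset = collapse_replicates(mat).subset_samples(["s0", "s2"])
        pd.testing.assert_frame_equal(subset_then_collapse.values, collapse_then_subset.values)


class TestQuantileNormalize:
    def test_two_by_two_worked_example(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]}, index=["a", "b"]), "collapsed"
        )
        out = quantile_normalize(mat)
        assert out.values["s1"].tolist() == [1.5, 3.5]
        assert out.values["s2"].tolist() == [1.5, 3.5]

    def test_identical_columns_unchanged(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [5.0, 1.0, 3.0], "s2": [5.0, 1.0, 3.0]}, index=list("abc")),
            "collapsed",
        )
        out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_single_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            quantile_normalize(
                ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"]), "collapsed")
            )

    def test_ties_share_reference_mean(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]}, index=list("abc")),
            "collapsed",
        )
        out = quantile_normalize(mat)
        ref = np.sort(mat.values.to_numpy(), axis=0).mean(axis=1)
        assert out.values.loc["a", "s1"] == out.values.loc["b", "s1"] == pytest.approx(
            ref[:2].mean()
        )

    @settings(max_examples=25, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 20), st.integers(2, 6)),
            elements=st.floats(0.01, 1e4, allow_nan=False),
            unique=True,  # idempotence is exact only for tie-free columns
        )
    )
    def test_idempotent_and_rank_preserving(self, arr):
        mat = ExpressionMatrix(
            pd.DataFrame(
                arr,
                index=[f"m{i}" for i in range(arr.shape[0])],
                columns=[f"s{j}" for j in range(arr.shape[1])],
            ),
            "collapsed",
        )
        once = quantile_normalize(mat)
        twice = quantile_normalize(
            ExpressionMatrix(once.values, "collapsed")
        )
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(), rtol=1e-12)
        # rank order preserved within each sample (up to ties)
        for j in range(arr.shape[1]):
            before = arr[:, j]
            after = once.values.to_numpy()[:, j]
            for a in range(len(before)):
                for b in range(len(before)):
                    if before[a] < before[b]:
                        assert after[a] <= after[b]

    def test_column_multisets_identical_after_normalization(self):
        rng = np.random.default_rng(5)
        arr = rng.lognormal(3, 1, (50, 6))
        mat = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"m{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(6)]),
            "collapsed",
        )
        out = quantile_normalize(mat).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)


class TestLog2:
    def test_values_and_round_trip(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [8.0], "s2": [1.0]}, index=["a"]), "normalized"
        )
        out = log2_transform(mat)
        assert out.values.iloc[0].tolist() == [3.0, 0.0]
        rng = np.random.default_rng(1)
        x = rng.uniform(-5, 5, (4, 3))
        mat2 = ExpressionMatrix(
            pd.DataFrame(np.exp2(x), index=list("abcd"), columns=["s1", "s2", "s3"]),
            "normalized",
        )
        np.testing.assert_allclose(log2_transform(mat2).values.to_numpy(), x)

    def test_nonpositive_value_names_row_and_column(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["a"]), "normalized"
        )
        with pytest.raises(DataError, match="s2"):
            log2_transform(mat)


class TestNormalityScreen:
    def test_gaussian_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(100, 5, (500, 534))
        mat = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"m{i}" for i in range(500)],
                         columns=[f"s{j}" for j in range(534)]),
            "normalized",
        )
        rep = normality_screen(mat, alpha=0.05)
        assert rep.frac_reject_linear == pytest.approx(0.05, abs=0.02)

    def test_lognormal_rejected_more_on_linear_scale(self):
        rng = np.random.default_rng(3)
        arr = np.exp2(rng.normal(8, 1, (200, 534)))
        mat = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"m{i}" for i in range(200)],
                         columns=[f"s{j}" for j in range(534)]),
            "normalized",
        )
        rep = normality_screen(mat)
        assert rep.frac_reject_linear > rep.frac_reject_log2

    def test_constant_row_flagged_not_applicable(self):
        arr = np.vstack([np.full(10, 3.0), np.random.default_rng(4).normal(5, 1, 10)])
        mat = ExpressionMatrix(
            pd.DataFrame(arr, index=["const", "ok"], columns=[f"s{j}" for j in range(10)]),
            "normalized",
        )
        rep = normality_screen(mat)
        assert not rep.table.loc["const", "usable"]
        assert np.isnan(rep.table.loc["const", "p_linear"])
        assert rep.table.loc["ok", "usable"]
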