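"""Differential-expression statistics: t-test, exact Wilcoxon, BH, AUC, genome-wide run."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirprospect.diffexp import (
    CohortSplit,
    benjamini_hochberg,
    roc_auc,
    run_diffexp,
    t_test_two_tailed,
    wilcoxon_exact,
)
from mirprospect.exceptions import ConfigurationError, StructuralError
from mirprospect.normalize import preprocess

from conftest import make_log2_matrix


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_two_tailed([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_near_separation_drives_p_to_zero(self):
        x = np.array([0, 0, 0, 0]) + 1e-9 * np.array([1, -1, 1, -1])
        y = np.array([1, 1, 1, 1]) + 1e-9 * np.array([-1, 1, -1, 1])
        _, p = t_test_two_tailed(x, y)
        assert p < 1e-10

    def test_pooled_closed_form_oracle(self):
        # pooled t for (1,2,3,4) vs (3,4,5,6): t = -2/sqrt(5/6), df = 6
        t, p = t_test_two_tailed([1, 2, 3, 4], [3, 4, 5, 6], equal_var=True)
        t_expected = -2 / math.sqrt(5 / 6)
        p_expected = 2 * stats.t.sf(abs(t_expected), 6)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(p_expected)  # = 0.070988...

    def test_constant_unequal_groups_flagged_degenerate(self):
        with pytest.warns(UserWarning):
            t, p = t_test_two_tailed([0.0, 0.0], [1.0, 1.0])
        assert p == 0.0 and np.isinf(t)

    @settings(max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        st.lists(st.floats(-100, 100), min_size=3, max_size=8),
        st.floats(-50, 50),
        st.floats(0.1, 20),
    )
    def test_invariance_to_shift_and_positive_scale(self, x, y, shift, scale):
        x, y = np.asarray(x), np.asarray(y)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return
        _, p0 = t_test_two_tailed(x, y)
        _, p1 = t_test_two_tailed(scale * (x + shift), scale * (y + shift))
        assert p1 == pytest.approx(p0, rel=1e-9, abs=1e-12)


class TestWilcoxon:
    def test_extreme_arrangement(self):
        w, p = wilcoxon_exact([1, 2, 3], [4, 5, 6], method="exact")
        assert p == pytest.approx(2 / 20)  # 2 extreme arrangements of C(6,3)

    def test_complete_tie_of_singletons(self):
        _, p = wilcoxon_exact([5], [5], method="exact")
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            wilcoxon_exact([], [1.0])

    def test_matches_brute_force_enumeration_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n1 = rng.integers(1, 6)
            n2 = rng.integers(1, 13 - n1 - 1)
            pooled = rng.integers(0, 4, n1 + n2).astype(float)  # heavy ties
            x, y = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_exact(x, y, method="exact")
            # independent brute force over all labelings
            ranks = stats.rankdata(pooled)
            mu = n1 * (len(pooled) + 1) / 2
            obs = abs(ranks[:n1].sum() - mu)
            hits = total = 0
            for combo in itertools.combinations(range(len(pooled)), int(n1)):
                total += 1
                if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-12:
                    hits += 1
            assert p == pytest.approx(hits / total)

    def test_exact_and_normal_agree_for_large_untied_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.normal(0, 1, 50)
            y = rng.normal(0.2, 1, 50)
            _, pe = wilcoxon_exact(x, y, method="exact")
            _, pa = wilcoxon_exact(x, y, method="normal")
            assert abs(pe - pa) < 0.005


class TestBenjaminiHochberg:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged_and_all_ones(self):
        assert benjamini_hochberg([0.3]).tolist() == [0.3]
        assert benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            benjamini_hochberg([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), expected)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_rank_monotone(self, p):
        q = benjamini_hochberg(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestRocAuc:
    def test_perfect_separation_and_ties(self):
        assert roc_auc([3, 4], [1, 2]) == 1.0
        assert roc_auc([2, 2], [2, 2]) == 0.5

    def test_interleaved_pairs(self):
        # concordant pairs: only (3 > 2) of the four case/control pairs
        assert roc_auc([1, 3], [2, 4]) == pytest.approx(0.25)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
        st.lists(st.floats(-10, 10), min_size=1, max_size=10),
    )
    def test_symmetry(self, x, y):
        assert roc_auc(x, y) == pytest.approx(1 - roc_auc(y, x))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 30)
        assert roc_auc(np.exp(x), np.exp(y)) == pytest.approx(roc_auc(x, y))


class TestRunDiffexp:
    def test_unknown_sample_rejected(self, planted_small):
        mat = preprocess(planted_small.expression)
        with pytest.raises(StructuralError):
            run_diffexp(mat, CohortSplit(["nope", "nah"], mat.sample_ids[:2]))

    def test_planted_markers_recovered_and_tests_concordant(self, planted_small):
        ds = planted_small
        mat = preprocess(ds.expression)
        de = run_diffexp(mat, CohortSplit.from_annotation(ds.annotation))
        truth = set(ds.truth.mirna_id)
        top = set(de.table.nsmallest(len(truth), "q_t").index)
        assert len(top & truth) / len(truth) > 0.5  # planted markers dominate the top ranks
        assert de.concordance_r > 0.5
        # BH never below raw p, for both families
        assert (de.table.q_t >= de.table.p_t - 1e-15).all()
        assert (de.table.q_w >= de.table.p_w - 1e-15).all()
        # fold-change orientation: down-regulation in cases gives FC > 1
        down = de.table.log2_fc < 0
        assert (de.table.loc[down, "fold_change"] > 1).all()

    def test_null_data_rarely_yields_bh_discoveries(self):
        # under the global null a seed has ~5% chance of any BH discovery
        from mirprospect.synth import SynthConfig, generate

        seeds_with_discoveries = 0
        for seed in range(8, 14):
            ds = generate(SynthConfig(n_mirnas=300, n_cases=20, n_controls=80, frac_de=0.0,
                                      n_replicates_per_probe=1, seed=seed))
            mat = preprocess(ds.expression)
            de = run_diffexp(mat, CohortSplit.from_annotation(ds.annotation))
            seeds_with_discoveries += int((de.table.q_t < 0.05).any())
        assert seeds_with_discoveries <= 1

    def test_exact_wilcoxon_used_for_tiny_cohorts(self):
        rng = np.random.default_rng(14)
        mat = make_log2_matrix(rng.normal(8, 1, (20, 8)))
        split = CohortSplit(mat.sample_ids[:4], mat.sample_ids[4:])
        de = run_diffexp(mat, split, exact_threshold=12)
        for mid in mat.feature_ids[:5]:
            x2 = mat.values.loc[mid, split.cohort2_ids]
            x1 = mat.values.loc[mid, split.cohort1_ids]
            _, p = wilcoxon_exact(x2, x1, method="exact")
            assert de.table.loc[mid, "p_w"] == pytest.approx(p)

    def test_volcano_table_conventions(self, planted_small):
        mat = preprocess(planted_small.expression)
        de = run_diffexp(mat, CohortSplit.from_annotation(planted_small.annotation))
        v = de.volcano_table()
        assert set(v.status.unique()) <= {"ns", "up_in_cohort1", "up_in_cohort2"}
        assert (v.loc[v.status == "ns", "p"] >= 0.05).all()
        assert (v.loc[v.status == "up_in_cohort1", "log2_fc"] < 0).all()
        assert np.isfinite(v.attrs["bh_line_neg_log10_p"])
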