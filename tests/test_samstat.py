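"""Moderated d-statistic, s0 selection, permutation null, FDR machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from samflow import (
    AnalysisError,
    Design,
    DesignError,
    call_significant,
    choose_s0,
    compute_d,
    dstat_density,
    estimate_fdr_table,
    permute_null,
    sam_analysis,
)
from tests.conftest import make_matrix


def two_group_design(n1, n2, g1="A", g2="B"):
    groups = {f"s{j}": (g1 if j < n1 else g2) for j in range(n1 + n2)}
    return Design((g1, g2), groups)


def direct_d(x1, x2, s0):
    """Independent elementwise oracle for the moderated d formula."""
    n1, n2 = len(x1), len(x2)
    r = np.mean(x1) - np.mean(x2)
    ss = np.sum((x1 - np.mean(x1)) ** 2) + np.sum((x2 - np.mean(x2)) ** 2)
    s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return r, s, r / (s + s0)


class TestComputeD:
    def test_hand_worked_example(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = compute_d(m, two_group_design(3, 3), s0=0.0)
        assert res["r"].iloc[0] == pytest.approx(-3.0)
        assert res["s"].iloc[0] == pytest.approx(0.8165, abs=1e-4)
        assert res["d"].iloc[0] == pytest.approx(-3.674, abs=1e-3)

    def test_equal_group_means_give_zero_d(self):
        m = make_matrix([[1.0, 3.0, 2.0, 1.0, 2.0, 3.0]])
        res = compute_d(m, two_group_design(3, 3), s0=0.0)
        assert res["d"].iloc[0] == 0.0

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 16))
        m = make_matrix(vals)
        for s0 in (0.0, 0.1, 1.0):
            res = compute_d(m, two_group_design(8, 8), s0=s0)
            for i in range(50):
                r, s, d = direct_d(vals[i, :8], vals[i, 8:], s0)
                assert res["r"].iloc[i] == pytest.approx(r, abs=1e-12)
                assert res["s"].iloc[i] == pytest.approx(s, abs=1e-12)
                assert res["d"].iloc[i] == pytest.approx(d, abs=1e-12)

    def test_s0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(30, 12))
        res = compute_d(make_matrix(vals), two_group_design(6, 6), s0=0.0)
        t = stats.ttest_ind(vals[:, :6], vals[:, 6:], axis=1).statistic
        np.testing.assert_allclose(res["d"].to_numpy(), t, atol=1e-12)

    def test_shrinkage_monotone_in_s0(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(20, 10)))
        design = two_group_design(5, 5)
        prev = np.abs(compute_d(m, design, s0=0.0)["d"].to_numpy())
        for s0 in (0.5, 2.0, 10.0):
            cur = np.abs(compute_d(m, design, s0=s0)["d"].to_numpy())
            assert (cur <= prev + 1e-15).all()
            prev = cur
        assert (np.abs(compute_d(m, design, s0=1e6)["d"]) < 1e-4).all()

    def test_tiny_group_rejected(self):
        with pytest.raises(DesignError):
            two_group_design(1, 5)

    def test_zero_variance_with_zero_s0_warns_inf(self):
        m = make_matrix([[1.0, 1.0, 2.0, 2.0]])
        with pytest.warns(UserWarning):
            res = compute_d(m, two_group_design(2, 2), s0=0.0)
        assert res["d"].iloc[0] == -np.inf


class TestChooseS0:
    @staticmethod
    def oracle_cv(r, s, cand, n_windows):
        # independent re-implementation of the window-MAD CV criterion
        order = np.argsort(s, kind="stable")
        windows = np.array_split(order, n_windows)
        d = r / (s + cand)
        mads = [np.median(np.abs(d[w] - np.median(d[w]))) for w in windows]
        return np.std(mads, ddof=1) / np.mean(mads)

    def test_homoscedastic_selects_smallest_candidates(self):
        rng = np.random.default_rng(3)
        s = np.full(2000, 0.5) + rng.normal(0, 0.01, 2000)
        r = rng.normal(0, 0.5, 2000)
        s0 = choose_s0(r, s)
        # CV is already flat: selected s0 must be at or near the 0th percentile
        assert s0 <= np.percentile(s, 10)

    def test_mean_variance_dependence_selects_positive_s0(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.05, 2.0, 3000)
        # r drawn independently of s, so d = r/(s+s0) blows up at small s
        # unless a positive fudge factor damps it
        r = rng.normal(0, 0.5, 3000)
        s0 = choose_s0(r, s)
        assert s0 > np.percentile(s, 1)
        cv_sel = self.oracle_cv(r, s, s0, 100)
        cv_zero = self.oracle_cv(r, s, np.percentile(s, 0), 100)
        assert cv_sel <= cv_zero + 1e-12

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0.1, 1.0, 500)
        r = rng.normal(size=500)
        s0 = choose_s0(r, s, candidate_percentiles=[50])
        assert s0 == pytest.approx(np.percentile(s, 50))

    def test_degenerate_scatter_returns_zero(self):
        with pytest.warns(UserWarning):
            assert choose_s0(np.ones(100), np.ones(100)) == 0.0


class TestPermuteNull:
    def test_full_enumeration_3v3(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(40, 6)))
        null = permute_null(m, two_group_design(3, 3), B=100, seed=0)
        assert null.exhaustive and null.n_assignments == 20
        assert null.d_sorted.shape == (20, 40)

    def test_seed_reproducible_sampling(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(30, 16)))
        design = two_group_design(8, 8)
        a = permute_null(m, design, B=50, seed=3)
        b = permute_null(m, design, B=50, seed=3)
        np.testing.assert_array_equal(a.d_sorted, b.d_sorted)
        assert not a.exhaustive

    def test_null_order_statistics_hug_identity(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(500, 12)))
        design = two_group_design(6, 6)
        null = permute_null(m, design, B=500, seed=0)
        d_obs = np.sort(compute_d(m, design, s0=0.0)["d"].to_numpy())
        # Monte Carlo envelope: interior order statistics hug the identity
        # line; the few extreme ones are allowed their larger sampling noise
        dev = np.abs(d_obs - null.dbar)
        assert dev[10:-10].max() < 0.5
        assert dev.max() < 2.0

    def test_b_below_one_rejected(self):
        m = make_matrix(np.random.default_rng(9).normal(size=(10, 6)))
        with pytest.raises(AnalysisError):
            permute_null(m, two_group_design(3, 3), B=0)


@pytest.fixture(scope="module")
def null_case():
    rng = np.random.default_rng(10)
    m = make_matrix(rng.normal(size=(400, 12)))
    design = two_group_design(6, 6)
    d = compute_d(m, design, s0=0.0)["d"]
    null = permute_null(m, design, B=300, seed=1)
    return d, null


class TestFdrTable:
    def test_huge_delta_zero_calls_na(self, null_case):
        d, null = null_case
        table = estimate_fdr_table(d, null, deltas=[np.inf])
        assert table["n_called"].iloc[0] == 0
        assert np.isnan(table["fdr"].iloc[0])

    def test_delta_zero_on_null_fdr_near_one(self, null_case):
        d, null = null_case
        table = estimate_fdr_table(d, null, deltas=[0.0])
        assert table["fdr"].iloc[0] > 0.8

    def test_fdr_monotone_nonincreasing(self, null_case):
        d, null = null_case
        table = estimate_fdr_table(d, null)
        vals = table["fdr"].dropna().to_numpy()
        assert (np.diff(vals) <= 1e-12).all()

    def test_dbar_nondecreasing(self, null_case):
        _, null = null_case
        assert (np.diff(null.dbar) >= 0).all()


class TestCallSignificant:
    def test_target_zero_on_null_no_calls(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(size=(300, 12)))
        design = two_group_design(6, 6)
        res = sam_analysis(m, design, target_fdrs=(0.0,), B=200, seed=0)
        assert len(res.called_ids(0.0)) == 0

    def test_calls_nested_as_target_decreases(self, small_cohort):
        from samflow import filter_low_expression, quantile_normalize

        m, _, _ = small_cohort
        m = filter_low_expression(quantile_normalize(m), 4.0)
        design = Design.from_annotations(m, "AU", "AI")
        res = sam_analysis(m, design, target_fdrs=(0.2, 0.1, 0.05, 0.01), B=150, seed=0)
        prev = None
        for fdr in (0.01, 0.05, 0.1, 0.2):
            cur = set(res.called_ids(fdr))
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_empty_table_rejected(self):
        with pytest.raises(AnalysisError):
            call_significant(pd.DataFrame(), pd.Series(dtype=float), 0.05)


class TestDesignFromAnnotations:
    def test_condition_restriction_and_labels(self, small_cohort):
        m, _, _ = small_cohort
        d_all = Design.from_annotations(m, "AU", "AI", labels=("AU-act", "AI-act"))
        d_s = Design.from_annotations(m, "AU", "AI", condition="S")
        assert d_all.contrast == ("AU-act", "AI-act")
        s1, s2 = d_all.group_samples()
        assert len(s1) == 16 and len(s2) == 15
        s1s, s2s = d_s.group_samples()
        assert len(s1s) == 8 and len(s2s) == 8

    def test_combined_groups_merge_conditions(self, small_cohort):
        # label merging: AU-act is the union of AU-S and AU-NS samples
        m, _, _ = small_cohort
        d_all = Design.from_annotations(m, "AU", "AI", labels=("AU-act", "AI-act"))
        s1, _ = d_all.group_samples()
        conds = m.samples.loc[s1, "condition"]
        assert set(conds) == {"S", "NS"}


def test_density_summary_integrates_to_one(small_cohort):
    m, _, _ = small_cohort
    design = Design.from_annotations(m, "AU", "AI")
    res = sam_analysis(m, design, target_fdrs=(0.1,), B=100, seed=0)
    dens = dstat_density(res)
    for col in ("observed", "expected"):
        integral = np.trapezoid(dens[col], dens["d"])
        assert integral == pytest.approx(1.0, abs=1e-3)
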