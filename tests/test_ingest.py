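"""Matrix IO, quantile normalization, low-intensity filtering, outlier QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from samflow import (
    AnalysisError,
    SchemaError,
    SimConfig,
    detect_low_cutoff,
    detect_outlier_arrays,
    filter_low_expression,
    generate_cohort,
    quantile_normalize,
    read_matrix,
    read_sample_sheet,
)
from tests.conftest import make_matrix


class TestIO:
    def test_matrix_round_trip(self, tmp_path):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = read_matrix(path)
        pd.testing.assert_frame_equal(back.values, m.values)

    def test_duplicate_probeset_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("probeset_id\ts0\ns1\t1.0\ns1\t2.0\n")
        with pytest.raises(SchemaError, match="duplicate probeset"):
            read_matrix(path)

    def test_non_numeric_named(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("probeset_id\ts0\ng1\t1.0\ng2\toops\n")
        with pytest.raises(SchemaError, match="s0"):
            read_matrix(path)

    def test_sample_sheet_missing_sample_errors(self, tmp_path):
        m = make_matrix(np.arange(6.0).reshape(2, 3))
        sheet = tmp_path / "sheet.tsv"
        sheet.write_text("sample_id\tphenotype\tcondition\ns0\tAU\tS\ns1\tAI\tS\n")
        with pytest.raises(SchemaError, match="missing"):
            read_sample_sheet(sheet, m)

    def test_sample_sheet_joined_by_id_not_order(self, tmp_path):
        m = make_matrix(np.arange(6.0).reshape(2, 3))
        sheet = tmp_path / "sheet.tsv"
        sheet.write_text(
            "sample_id\tphenotype\tcondition\n"
            "s2\tAI\tNS\ns0\tAU\tS\ns1\tAU\tNS\n"
        )
        annotated = read_sample_sheet(sheet, m)
        assert list(annotated.samples.index) == ["s0", "s1", "s2"]
        assert annotated.samples.loc["s2", "phenotype"] == "AI"


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_two_column_example(self):
        m = make_matrix(np.column_stack([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_all_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(50, 6)))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(40, 4))
        out = quantile_normalize(make_matrix(vals)).values.to_numpy()
        for j in range(4):
            assert (np.argsort(vals[:, j], kind="stable")
                    == np.argsort(out[:, j], kind="stable")).all()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        arrays(
            np.float64,
            (12, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=64),
        )
    )
    def test_idempotent(self, vals):
        once = quantile_normalize(make_matrix(vals))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-9
        )

    def test_single_sample_warns_noop(self):
        m = make_matrix([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestLowCutoff:
    def test_unimodal_falls_back_to_default(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(7.0, 0.5, size=(2000, 6)))
        assert detect_low_cutoff(m) == 4.0

    def test_bimodal_dip_located(self):
        m, _, _ = _cohort(n_genes=4000, seed=4)
        cut = detect_low_cutoff(m)
        assert 3.5 < cut < 6.5

    def test_dip_matches_generating_mixture(self):
        # oracle: the density minimum of the generating two-component mixture
        from scipy.optimize import minimize_scalar
        from scipy.stats import norm

        cfg = SimConfig(n_genes=8000, n_de=0, seed=6)
        m, _ = generate_cohort(cfg)
        n = sum(cfg.group_sizes.values())
        sigma = np.sqrt(cfg.mode_spread**2 + cfg.gene_sd_scale**2 / n)
        f = cfg.frac_low_expressed

        def dens(x):
            return f * norm.pdf(x, cfg.low_mode_mean, sigma) + (1 - f) * norm.pdf(
                x, cfg.high_mode_mean, sigma
            )

        expected = minimize_scalar(
            dens, bounds=(cfg.low_mode_mean, cfg.high_mode_mean), method="bounded"
        ).x
        assert abs(detect_low_cutoff(m) - expected) < 0.5

    def test_all_high_default_removes_nothing(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(11.0, 0.3, size=(1000, 5)))
        cut = detect_low_cutoff(m)
        assert cut == 4.0
        assert filter_low_expression(m, cut).n_genes == 1000


class TestFilterLowExpression:
    def test_minus_inf_identity(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        out = filter_low_expression(m, -np.inf)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_boundary_strictly_below_removed(self):
        m = make_matrix([[3.9, 3.9], [4.0, 4.0], [4.1, 4.1]])
        out = filter_low_expression(m, 4.0)
        assert list(out.probeset_ids) == ["g1", "g2"]

    def test_planted_low_fraction_removed(self):
        m, truth, _ = _cohort(n_genes=5000, seed=8)
        out = filter_low_expression(m, 5.0)
        removed_frac = 1 - out.n_genes / m.n_genes
        assert removed_frac == pytest.approx(truth["is_low"].mean(), abs=0.02)

    def test_monotone_in_cutoff(self):
        m, _, _ = _cohort(n_genes=500, seed=9)
        loose = set(filter_low_expression(m, 3.0).probeset_ids)
        strict = set(filter_low_expression(m, 5.0).probeset_ids)
        assert strict <= loose

    def test_all_removed_errors(self):
        m = make_matrix([[1.0, 1.0]])
        with pytest.raises(AnalysisError):
            filter_low_expression(m, 99.0)


class TestOutlierArrays:
    def test_identical_arrays_none_flagged(self):
        col = np.random.default_rng(0).normal(size=200)
        m = make_matrix(np.column_stack([col] * 6))
        assert detect_outlier_arrays(m).flagged_outliers == []

    def test_planted_noise_array_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=500)
        coherent = base[:, None] + rng.normal(0, 0.2, size=(500, 15))
        noise = rng.normal(size=(500, 1))
        m = make_matrix(np.hstack([coherent, noise]))
        report = detect_outlier_arrays(m)
        assert report.flagged_outliers == ["s15"]

    def test_too_few_samples_empty_report(self):
        m = make_matrix(np.random.default_rng(2).normal(size=(50, 3)))
        with pytest.warns(UserWarning):
            report = detect_outlier_arrays(m)
        assert report.flagged_outliers == []

    def test_false_positive_rate_on_homogeneous_cohorts(self):
        # guarantee: <= 5% of arrays flagged across homogeneous simulations
        rng = np.random.default_rng(3)
        flagged = total = 0
        for _ in range(200):
            base = rng.normal(size=150)
            vals = base[:, None] + rng.normal(0, 0.3, size=(150, 12))
            report = detect_outlier_arrays(make_matrix(vals))
            flagged += len(report.flagged_outliers)
            total += 12
        assert flagged / total <= 0.05

    def test_cap_at_twenty_percent(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=300)
        coherent = base[:, None] + rng.normal(0, 0.1, size=(300, 6))
        noise = rng.normal(size=(300, 4))
        m = make_matrix(np.hstack([coherent, noise]))
        report = detect_outlier_arrays(m)
        assert len(report.flagged_outliers) <= 2  # 20% of 10


def _cohort(n_genes, seed):
    cfg = SimConfig(n_genes=n_genes, n_de=0, seed=seed)
    m, truth = generate_cohort(cfg)
    return m, truth, cfg
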