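import numpy as np
import pytest

import shrinklls.regression
from shrinklls import (
    ImputeConfig,
    ImputeReport,
    ShrinkageConfig,
    fit_and_impute,
    ills_impute,
    lls_impute,
    mask_random,
    matrix_from_values,
    missing_profile,
    row_average_impute,
    score_imputation,
    select_by_threshold,
    select_k_nearest,
    slls_impute,
)
from shrinklls.imputers import _eligible_candidates
from shrinklls.io_matrix import ExpressionMatrix


def _masked(matrix, rate=0.05, seed=0):
    return mask_random(matrix, rate, seed)


class TestLLS:
    def test_complete_matrix_is_identity_with_notice(self, clustered_matrix):
        report = ImputeReport()
        out = lls_impute(clustered_matrix, ImputeConfig(method="lls"), report)
        assert np.array_equal(out.values, clustered_matrix.values)
        assert report.notices

    def test_exact_on_noiseless_rank1(self, rank1_matrix):
        masked, record = _masked(rank1_matrix)
        out = lls_impute(masked, ImputeConfig(method="lls", k=10))
        assert score_imputation(out, record) < 1e-6

    def test_observed_entries_bit_identical_and_mask_cleared(self, clustered_matrix):
        masked, _ = _masked(clustered_matrix)
        obs = ~masked.missing_mask
        out = lls_impute(masked, ImputeConfig(method="lls", k=20))
        assert np.array_equal(out.values[obs], masked.values[obs])
        assert not out.missing_mask.any()
        assert not np.isnan(out.values).any()

    def test_matches_step_by_step_composition(self, clustered_matrix):
        """Whole-matrix LLS equals an independent re-implementation that
        drives the module operations target by target."""
        masked, _ = _masked(clustered_matrix, rate=0.05, seed=3)
        cfg = ImputeConfig(method="lls", k=15, shrinkage=ShrinkageConfig())
        out = lls_impute(masked, cfg)
        expected = masked.values.copy()
        mask = masked.missing_mask
        for i in np.flatnonzero(mask.any(axis=1)):
            usable = np.flatnonzero(~mask[i])
            cands = _eligible_candidates(mask, i)
            nbrs = select_k_nearest(masked, i, cands, cfg.k, usable)
            est, _ = fit_and_impute(masked, nbrs, i, cfg.shrinkage)
            expected[i, np.flatnonzero(mask[i])] = est
        assert np.array_equal(out.values, expected)

    def test_forced_factor_one_equals_unshrunk(self, clustered_matrix, monkeypatch):
        masked, _ = _masked(clustered_matrix)
        monkeypatch.setattr(
            shrinklls.regression,
            "shrink_coefficients",
            lambda x, n_tilde, config: (x, 1.0),
        )
        on = lls_impute(masked, ImputeConfig(method="lls", k=20, shrinkage=ShrinkageConfig()))
        off = lls_impute(masked, ImputeConfig(method="lls", k=20))
        assert np.array_equal(on.values, off.values)

    def test_gene_with_too_few_observations_uses_fallback(self):
        vals = np.array(
            [
                [1.0, np.nan, np.nan, np.nan],
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
            ]
        )
        report = ImputeReport()
        out = lls_impute(matrix_from_values(vals), ImputeConfig(method="lls", k=2), report)
        assert 0 in report.fallback_targets
        assert np.allclose(out.values[0, 1:], 1.0)  # row average of the single value


class TestSLLS:
    def test_missing_profile_toy_values(self):
        vals = np.ones((5, 4))
        vals[2, 0] = np.nan
        vals[3, [0, 1]] = np.nan
        vals[4, [0, 1, 2]] = np.nan
        prof = missing_profile(matrix_from_values(vals))
        assert np.array_equal(prof.per_gene_missing_count, [0, 0, 1, 2, 3])
        assert np.allclose(prof.per_gene_missing_rate, [0, 0, 0.25, 0.5, 0.75])
        assert prof.reuse_threshold == pytest.approx(0.5, abs=1e-15)

    def test_reuse_pool_is_strictly_sub_threshold(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(8, 4))
        vals[2, 0] = np.nan  # rate 0.25
        vals[3, [0, 1]] = np.nan  # rate 0.50
        vals[4, [0, 1, 2]] = np.nan  # rate 0.75, r0 = 0.5
        report = ImputeReport()
        slls_impute(matrix_from_values(vals), ImputeConfig(method="slls", k=3), report)
        assert report.reused_genes == [2]  # only the rate-0.25 gene re-enters G1

    def test_visits_targets_in_non_decreasing_missing_rate(self, clustered_matrix):
        masked, _ = _masked(clustered_matrix, rate=0.15, seed=5)
        prof = missing_profile(masked)
        report = ImputeReport()
        slls_impute(masked, ImputeConfig(method="slls", k=10), report)
        rates = prof.per_gene_missing_rate[report.visit_order]
        assert np.all(np.diff(rates) >= 0)
        assert sorted(report.visit_order) == list(
            np.flatnonzero(masked.missing_mask.any(axis=1))
        )

    def test_single_incomplete_gene_equals_lls(self, clustered_matrix):
        vals = clustered_matrix.values.copy()
        vals[7, 2] = np.nan
        m = matrix_from_values(vals)
        a = slls_impute(m, ImputeConfig(method="slls", k=12))
        b = lls_impute(m, ImputeConfig(method="lls", k=12))
        assert np.array_equal(a.values, b.values)

    def test_exact_on_noiseless_rank1(self, rank1_matrix):
        masked, record = _masked(rank1_matrix)
        out = slls_impute(masked, ImputeConfig(method="slls", k=10))
        assert score_imputation(out, record) < 1e-6

    def test_all_genes_incomplete_bootstraps(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=4)
        vals = np.vstack([base * s for s in (1.0, 2.0, 3.0, 4.0, 5.0)])
        for i in range(5):
            vals[i, i % 4] = np.nan
        report = ImputeReport()
        out = slls_impute(matrix_from_values(vals), ImputeConfig(method="slls", k=3), report)
        assert not np.isnan(out.values).any()
        assert report.fallback_targets  # the bootstrap gene had no candidates


class TestILLS:
    def test_exact_on_noiseless_rank1(self, rank1_matrix):
        # run to convergence: the exactness property is about the fixed
        # point, not the default early-stopping rule
        masked, record = _masked(rank1_matrix)
        cfg = ImputeConfig(method="ills", max_iterations=20, convergence_tol=1e-9)
        out = ills_impute(masked, cfg)
        assert score_imputation(out, record) < 1e-6

    def test_single_iteration_matches_composition(self, clustered_matrix):
        """max_iterations=1 equals row-average init + one threshold-LLS pass
        recomposed externally from the module operations."""
        masked, _ = _masked(clustered_matrix, seed=4)
        cfg = ImputeConfig(method="ills", delta_ratio=1.0, max_iterations=1)
        out = ills_impute(masked, cfg)
        mask = masked.missing_mask
        filled = row_average_impute(masked)
        expected = filled.values.copy()
        work = ExpressionMatrix(
            list(masked.gene_ids), list(masked.condition_ids), filled.values.copy()
        )
        all_rows = np.arange(masked.n_genes)
        for i in np.flatnonzero(mask.any(axis=1)):
            usable = np.flatnonzero(~mask[i])
            if usable.size < 3:
                continue
            nbrs = select_by_threshold(work, i, all_rows, 1.0, usable)
            est, _ = fit_and_impute(masked, nbrs, i, None, values=work.values)
            expected[i, np.flatnonzero(mask[i])] = est
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_iteration_count_deterministic_and_capped(self, clustered_matrix):
        masked, _ = _masked(clustered_matrix, seed=6)
        cfg = ImputeConfig(method="ills", max_iterations=4, convergence_tol=1e-4)
        r1, r2 = ImputeReport(), ImputeReport()
        a = ills_impute(masked, cfg, r1)
        b = ills_impute(masked, cfg, r2)
        assert r1.iterations == r2.iterations <= 4
        assert np.array_equal(a.values, b.values)

    def test_observed_entries_untouched(self, clustered_matrix):
        masked, _ = _masked(clustered_matrix, seed=2)
        obs = ~masked.missing_mask
        out = ills_impute(masked, ImputeConfig(method="ills"))
        assert np.array_equal(out.values[obs], masked.values[obs])


class TestRowAverage:
    def test_simple_row_mean(self):
        out = row_average_impute(matrix_from_values([[1.0, np.nan, 3.0], [5.0, 5.0, 5.0]]))
        assert out.values[0, 1] == pytest.approx(2.0)

    def test_complete_matrix_identity(self, clustered_matrix):
        out = row_average_impute(clustered_matrix)
        assert np.array_equal(out.values, clustered_matrix.values)

    def test_fully_missing_gene_gets_column_means(self):
        vals = np.array(
            [[np.nan, np.nan, np.nan], [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]]
        )
        out = row_average_impute(matrix_from_values(vals))
        assert np.allclose(out.values[0], [2.0, 3.0, 4.0])


class TestDeterminism:
    @pytest.mark.parametrize("method", ["lls", "slls", "ills"])
    def test_repeated_runs_identical(self, clustered_matrix, method):
        masked, _ = _masked(clustered_matrix, seed=10)
        cfg = ImputeConfig(method=method, k=10, shrinkage=ShrinkageConfig())
        a = globals()[f"{method}_impute"](masked, cfg)
        b = globals()[f"{method}_impute"](masked, cfg)
        assert np.array_equal(a.values, b.values)
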