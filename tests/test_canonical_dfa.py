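"""Canonical discriminant analysis: algebraic identities, closed-form
oracles, independent-implementation agreement, and the classification
machinery."""

import numpy as np
import pandas as pd
import pytest
from actiphase.canonical_dfa import (
    bootstrap_dfa,
    canonical_stats_from_eigenvalues,
    classification_table,
    classify,
    fit_dfa,
    leave_one_out_cv,
    manova_screen,
    standardized_residual_scores,
    structure_matrix_report,
)
from actiphase.errors import SingularityError


def make_groups_data(seed, n_per_group=(12, 16, 6), p=5, separation=1.0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for g, n in enumerate(n_per_group):
        centre = rng.normal(0, separation, p)
        X.append(centre + rng.standard_normal((n, p)))
        y += [f"g{g}"] * n
    return np.vstack(X), np.array(y)


class TestStandardizedResidualScores:
    def _table(self, seed=5, n=34, p=4):
        rng = np.random.default_rng(seed)
        age = rng.uniform(20, 70, n)
        gender = (rng.random(n) < 0.5).astype(float)
        predictors = pd.DataFrame(
            {f"v{j}": 2 * age + 5 * gender + rng.standard_normal(n) * 10 for j in range(p)}
        )
        covariates = pd.DataFrame({"age": age, "gender": gender})
        return predictors, covariates

    def test_no_covariates_reduces_to_zscores(self):
        predictors, _ = self._table()
        out = standardized_residual_scores(predictors, None)
        raw = predictors.to_numpy()
        expected = (raw - raw.mean(0)) / raw.std(0, ddof=1)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_output_columns_standardized(self):
        predictors, covariates = self._table()
        out = standardized_residual_scores(predictors, covariates).to_numpy()
        np.testing.assert_allclose(out.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(0, ddof=1), 1, atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self):
        predictors, covariates = self._table()
        out = standardized_residual_scores(predictors, covariates).to_numpy()
        for col in ("age", "gender"):
            c = covariates[col] - covariates[col].mean()
            corr = out.T @ c / np.sqrt((out**2).sum(0) * (c @ c))
            np.testing.assert_allclose(corr, 0, atol=1e-10)

    def test_constant_predictor_named_in_error(self):
        predictors, covariates = self._table()
        predictors["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            standardized_residual_scores(predictors, covariates)


class TestManova:
    def test_identical_group_distributions_give_lambda_one(self):
        rng = np.random.default_rng(8)
        block = rng.standard_normal((15, 4))
        X = np.vstack([block, block])
        y = np.array(["a"] * 15 + ["b"] * 15)
        res = manova_screen(X, y)
        assert res.wilks == pytest.approx(1.0, abs=1e-10)
        assert res.f_stat == pytest.approx(0.0, abs=1e-8)

    def test_two_group_case_equals_hotelling_t2(self):
        X, y = make_groups_data(9, n_per_group=(14, 11), p=4, separation=0.8)
        res = manova_screen(X, y)
        # Hotelling's T^2 computed independently
        a, b = X[y == "g0"], X[y == "g1"]
        n1, n2 = len(a), len(b)
        pooled = ((n1 - 1) * np.cov(a.T) + (n2 - 1) * np.cov(b.T)) / (n1 + n2 - 2)
        diff = a.mean(0) - b.mean(0)
        t2 = (n1 * n2) / (n1 + n2) * diff @ np.linalg.solve(pooled, diff)
        p_dim = X.shape[1]
        f_hotelling = t2 * (n1 + n2 - p_dim - 1) / ((n1 + n2 - 2) * p_dim)
        assert res.f_stat == pytest.approx(f_hotelling, rel=1e-10)
        assert res.df1 == p_dim
        assert res.df2 == n1 + n2 - p_dim - 1

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        X, y = make_groups_data(10, n_per_group=(12, 16, 6), p=5, separation=0.7)
        res = manova_screen(X, y)
        frame = pd.DataFrame(X, columns=[f"v{j}" for j in range(5)])
        frame["grp"] = y
        mv = statsmodels.MANOVA.from_formula(
            " + ".join(frame.columns[:-1]) + " ~ grp", data=frame
        )
        table = mv.mv_test().results["grp"]["stat"]
        assert res.wilks == pytest.approx(table.loc["Wilks' lambda", "Value"], rel=1e-8)
        assert res.f_stat == pytest.approx(table.loc["Wilks' lambda", "F Value"], rel=1e-6)

    def test_separated_groups_are_significant(self):
        X, y = make_groups_data(11, separation=3.0)
        assert manova_screen(X, y).p_value < 0.001


class TestFitDfa:
    def test_identity_layer_from_published_eigenvalues(self):
        """λ = (3.04, 1.01) implies canonical correlations .87/.71, Wilks
        .12/.49-.50 and 75/25% of variance."""
        out = canonical_stats_from_eigenvalues([3.04, 1.01])
        np.testing.assert_allclose(np.round(out["canonical_correlations"], 2), [0.87, 0.71])
        np.testing.assert_allclose(np.round(out["pct_variance"], 0), [75, 25])
        assert out["wilks_lambda"][0] == pytest.approx(0.12, abs=0.005)
        assert out["wilks_lambda"][1] == pytest.approx(0.49, abs=0.01)

    def test_model_identities_hold_on_fits(self):
        """canonical_corr² = λ/(1+λ); Λ_k·Π(1+λ) = 1; Σ pct = 100;
        weighted centroid mean 0; within-group score variance 1."""
        for seed in range(6):
            X, y = make_groups_data(100 + seed, separation=1.2)
            model = fit_dfa(X, y)
            lam = model.eigenvalues
            np.testing.assert_allclose(
                model.canonical_correlations**2, lam / (1 + lam), atol=1e-12
            )
            for k in range(len(lam)):
                assert model.wilks_lambda[k] * np.prod(1 + lam[k:]) == pytest.approx(1.0)
            assert model.pct_variance.sum() == pytest.approx(100.0)
            weighted = model.group_sizes @ model.centroids
            np.testing.assert_allclose(weighted, 0, atol=1e-9)
            # pooled within-group variance of scores is 1
            scores = model.scores(X)
            w_var = np.zeros(model.n_functions)
            for g in model.groups:
                sub = scores[y == g]
                w_var += (len(sub) - 1) * sub.var(0, ddof=1)
            np.testing.assert_allclose(w_var / (len(y) - len(model.groups)), 1.0, atol=1e-9)

    def test_duplicated_relabeled_groups_have_zero_eigenvalues(self):
        rng = np.random.default_rng(14)
        block = rng.standard_normal((20, 4))
        X = np.vstack([block, block])
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = fit_dfa(X, y)
        np.testing.assert_allclose(model.eigenvalues, 0, atol=1e-10)

    def test_two_group_direction_matches_fisher_closed_form(self):
        X, y = make_groups_data(15, n_per_group=(20, 17), p=2, separation=1.5)
        model = fit_dfa(X, y)
        mu = [X[y == g].mean(0) for g in model.groups]
        w_inv_d = np.linalg.solve(model.pooled_cov, mu[0] - mu[1])
        direction = model.raw_coefficients[:, 0]
        cos = w_inv_d @ direction / np.sqrt((w_inv_d @ w_inv_d) * (direction @ direction))
        assert abs(cos) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_cases_is_singularity_error(self):
        X, y = make_groups_data(16, n_per_group=(5, 5, 4), p=13)
        with pytest.raises(SingularityError):
            fit_dfa(X, y)

    def test_structure_matrix_is_pooled_within_correlation(self):
        X, y = make_groups_data(17, separation=1.0)
        model = fit_dfa(X, y)
        scores = model.scores(X)
        p = X.shape[1]
        # independent computation: pooled within-group covariance of
        # (predictor, score) divided by pooled SDs
        for fn in range(model.n_functions):
            for j in range(p):
                sxx = sxy = syy = 0.0
                for g in model.groups:
                    xs = X[y == g][:, j]
                    ys = scores[y == g][:, fn]
                    sxx += ((xs - xs.mean()) ** 2).sum()
                    syy += ((ys - ys.mean()) ** 2).sum()
                    sxy += ((xs - xs.mean()) * (ys - ys.mean())).sum()
                assert model.structure_matrix[j, fn] == pytest.approx(
                    sxy / np.sqrt(sxx * syy), abs=1e-10
                )


class TestClassify:
    def test_group_centroid_rows_classify_to_own_group(self):
        X, y = make_groups_data(20, separation=2.5)
        model = fit_dfa(X, y, priors="equal")
        means = np.vstack([X[y == g].mean(0) for g in model.groups])
        np.testing.assert_array_equal(classify(model, means), model.groups)

    def test_oracle_agreement_with_sklearn_lda(self):
        """Pooled-covariance linear discriminant classification agrees
        with an independent implementation on 50 seeded datasets."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        for seed in range(50):
            X, y = make_groups_data(300 + seed, separation=0.9)
            model = fit_dfa(X, y, priors="proportional")
            ours = classify(model, X)
            lda = sklearn_da.LinearDiscriminantAnalysis(solver="svd")
            theirs = lda.fit(X, y).predict(X)
            assert (ours == theirs).all()

    def test_dimension_mismatch_raises(self):
        X, y = make_groups_data(21)
        model = fit_dfa(X, y)
        with pytest.raises(ValueError, match="dimension"):
            classify(model, X[:, :3])


class TestClassificationTable:
    def test_published_confusion_counts(self):
        """The study's 3x3 confusion table: 79.4% overall, 58/94/83%
        per group, Pearson chi2 36.21 with df 4."""
        y_true = (
            ["bipolar_depression"] * 12 + ["mania"] * 16 + ["mixed"] * 6
        )
        y_pred = (
            ["bipolar_depression"] * 7 + ["mania"] * 5
            + ["mania"] * 15 + ["mixed"] * 1
            + ["mania"] * 1 + ["mixed"] * 5
        )
        table = classification_table(y_true, y_pred)
        np.testing.assert_array_equal(
            table.counts, [[7, 5, 0], [0, 15, 1], [0, 1, 5]]
        )
        assert table.overall_accuracy == pytest.approx(100 * 27 / 34, abs=1e-9)
        np.testing.assert_allclose(
            np.round(table.per_group_accuracy), [58, 94, 83]
        )
        assert table.chi2 == pytest.approx(36.21, abs=0.005)
        assert table.df == 4

    def test_perfect_prediction(self):
        y = ["a"] * 12 + ["b"] * 16 + ["c"] * 6
        table = classification_table(y, y)
        assert table.overall_accuracy == 100.0
        np.testing.assert_array_equal(np.diag(table.counts), [12, 16, 6])
        assert np.trace(table.counts) == table.counts.sum()

    def test_row_sums_equal_group_sizes(self):
        rng = np.random.default_rng(23)
        y_true = rng.choice(["a", "b", "c"], 40)
        y_pred = rng.choice(["a", "b", "c"], 40)
        table = classification_table(y_true, y_pred)
        for i, g in enumerate(table.groups):
            assert table.counts[i].sum() == (y_true == g).sum()

    def test_unseen_predicted_label_rejected(self):
        with pytest.raises(ValueError, match="not in group set"):
            classification_table(["a", "a", "b"], ["a", "z", "b"])


class TestLeaveOneOut:
    def test_far_separated_clusters_classify_perfectly(self):
        X, y = make_groups_data(24, n_per_group=(10, 10), p=3, separation=25.0)
        table = leave_one_out_cv(X, y)
        assert table.overall_accuracy == 100.0
        assert table.mode == "leave_one_out"

    def test_row_sums_conserved(self):
        X, y = make_groups_data(25, n_per_group=(12, 16, 6), separation=0.5)
        table = leave_one_out_cv(X, y)
        for i, g in enumerate(table.groups):
            assert table.counts[i].sum() == (y == g).sum()
        assert table.n_unclassified == 0

    def test_loocv_not_more_optimistic_than_apparent_on_noise(self):
        X, y = make_groups_data(26, separation=0.0)
        model = fit_dfa(X, y)
        apparent = classification_table(y, classify(model, X))
        loocv = leave_one_out_cv(X, y)
        assert loocv.overall_accuracy <= apparent.overall_accuracy


class TestBootstrap:
    def test_deterministic_under_seed(self):
        X, y = make_groups_data(27, separation=1.5)
        a = bootstrap_dfa(X, y, n_boot=50, seed=123)
        b = bootstrap_dfa(X, y, n_boot=50, seed=123)
        np.testing.assert_array_equal(a.eigenvalues, b.eigenvalues)
        np.testing.assert_array_equal(a.accuracy_ci, b.accuracy_ci)

    def test_identity_resample_reproduces_full_fit(self, monkeypatch):
        """If the stratified resample returns every case once, the
        replicate equals the full-sample fit."""
        X, y = make_groups_data(28, separation=1.5)
        full = fit_dfa(X, y)

        class IdentityRng:
            def choice(self, idx, size, replace):
                return idx

        monkeypatch.setattr(np.random, "default_rng", lambda seed=None: IdentityRng())
        boot = bootstrap_dfa(X, y, n_boot=1, seed=0)
        np.testing.assert_allclose(boot.eigenvalues[0], full.eigenvalues, atol=1e-10)

    def test_ci_covers_full_sample_eigenvalue(self):
        X, y = make_groups_data(29, separation=2.0)
        full = fit_dfa(X, y)
        boot = bootstrap_dfa(X, y, n_boot=200, seed=7)
        lo, hi = boot.eigenvalue_ci[0]
        assert lo <= full.eigenvalues[0] <= hi


class TestStructureReport:
    def test_threshold_masks_small_loadings(self):
        X, y = make_groups_data(30, separation=1.0)
        model = fit_dfa(X, y)
        model.structure_matrix[0, 0] = 0.35
        model.structure_matrix[1, 0] = 0.29
        full, filtered = structure_matrix_report(model, threshold=0.3)
        assert filtered.iloc[0, 0] == pytest.approx(0.35)
        assert np.isnan(filtered.iloc[1, 0])
        assert full.iloc[1, 0] == pytest.approx(0.29)

    def test_zero_threshold_keeps_everything(self):
        X, y = make_groups_data(31)
        model = fit_dfa(X, y)
        full, filtered = structure_matrix_report(model, threshold=0.0)
        pd.testing.assert_frame_equal(full, filtered)
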