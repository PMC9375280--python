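"""Standardization, per-stage PCA, autoencoder, IQR features, logistic head."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cpetdx as cd
from cpetdx.latent import (
    AEModel,
    AutoencoderLogisticClassifier,
    PCALogisticClassifier,
    extract_features,
    fit_autoencoder,
    fit_logistic,
    fit_stage_pca,
    iqr,
    predict_heart_failure_probability,
    standardize_channels,
)
from cpetdx.schema import MODEL_CHANNELS


class TestStandardize:
    def test_training_pool_standardized(self, small_cohort):
        stats, transform = standardize_channels(small_cohort)
        pooled = np.vstack([transform(r) for r in small_cohort])
        assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(pooled.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_named_in_error(self, small_cohort):
        rigged = []
        for r in small_cohort:
            df = r.series.data.copy()
            df["hr"] = 100.0
            rigged.append(cd.PatientRecord(r.patient_id, cd.BreathSeries(df), r.label))
        with pytest.raises(ValueError, match="hr"):
            standardize_channels(rigged)

    def test_train_statistics_differ_from_self_statistics(self, small_cohort):
        """Leakage guard: standardizing a shifted held-out record with the
        training statistics is not the same as using its own statistics."""
        stats, transform = standardize_channels(small_cohort[:-1])
        held = small_cohort[-1]
        df = held.series.data.copy()
        df[list(MODEL_CHANNELS)] += 5.0  # shift every modeling channel
        shifted = cd.PatientRecord("s", cd.BreathSeries(df))
        by_train = transform(shifted)
        _, own_transform = standardize_channels([shifted])
        by_self = own_transform(shifted)
        assert not np.allclose(by_train, by_self, atol=1e-3)


class TestStagePCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 8))
        X = rng.normal(size=(300, 8)) @ A
        model = fit_stage_pca(X)
        # independent oracle: eigenvectors of the sample covariance
        cov = np.cov(X, rowvar=False, ddof=1)
        w, V = np.linalg.eigh(cov)
        top = V[:, np.argsort(w)[::-1][:3]].T
        for got, want in zip(model.components, top):
            sign = np.sign(got @ want)
            assert np.allclose(got, sign * want, atol=1e-6)

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 8))
        U = fit_stage_pca(X).components
        assert np.allclose(U @ U.T, np.eye(3), atol=1e-8)

    def test_rank_one_data(self):
        rng = np.random.default_rng(2)
        direction = rng.normal(size=8)
        X = rng.normal(size=(200, 1)) @ direction[None, :]
        X += 1e-6 * rng.normal(size=X.shape)  # avoid exactly degenerate SVD
        model = fit_stage_pca(X)
        assert model.explained_variance_ratio[0] >= 0.999

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_stage_pca(np.zeros((5, 8)))

    def test_projection_matches_matrix_multiply_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8))
        model = fit_stage_pca(X)
        scores = model.transform(X)
        assert np.allclose(scores, (X - model.mean) @ model.components.T, atol=1e-12)

    def test_loadings_rows_recover_unit_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 8))
        model = fit_stage_pca(X)
        basis = model.components + model.mean  # axes shifted to data frame
        assert np.allclose(model.transform(basis), np.eye(3), atol=1e-9)


class TestAutoencoder:
    def test_capacity_sufficient_subspace(self):
        """Data lying exactly in a 3-dim linear subspace reconstructs to
        MSE < 1e-2 (the bottleneck is wide enough)."""
        rng = np.random.default_rng(5)
        basis = np.linalg.qr(rng.normal(size=(8, 3)))[0]
        X = rng.normal(size=(400, 3)) @ basis.T
        model = fit_autoencoder(X, activation="identity", seed=0)
        assert model.reconstruction_mse(X) < 1e-2

    def test_loss_decreases(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 8)) @ rng.normal(size=(8, 8))
        model = fit_autoencoder(X, seed=0)
        assert model.loss_history[-1] <= model.loss_history[0]
        assert np.all(np.isfinite(model.loss_history))

    def test_linear_ae_approaches_pca_optimum(self):
        """With identity activations the reconstruction MSE approaches the
        PCA(3) linear optimum (within 10%) on correlated Gaussian data."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(8, 8)) * np.array([3, 2.5, 2, 0.5, 0.3, 0.2, 0.1, 0.1])
        X = rng.normal(size=(600, 8)) @ A.T
        model = fit_autoencoder(X, activation="identity", seed=0)
        from sklearn.decomposition import PCA
        pca = PCA(n_components=3).fit(X)
        pca_mse = float(np.mean((X - pca.inverse_transform(pca.transform(X))) ** 2))
        assert model.reconstruction_mse(X) <= 1.10 * pca_mse

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 8))
        m1 = fit_autoencoder(X, seed=3)
        m2 = fit_autoencoder(X, seed=3)
        assert np.allclose(m1.encode(X), m2.encode(X), atol=0)

    def test_small_pool_warns(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning, match="breaths"):
            fit_autoencoder(rng.normal(size=(50, 8)), max_epochs=10, seed=0)


class TestIQRAndFeatures:
    def test_worked_examples(self):
        assert iqr([5.0] * 10) == 0.0
        # linear-interpolation quantiles: Q1 = 2.75, Q3 = 6.25
        assert iqr([1, 2, 3, 4, 5, 6, 7, 8]) == pytest.approx(3.5)
        with pytest.raises(ValueError):
            iqr([1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
        shift=st.floats(-1e3, 1e3),
    )
    def test_affine_equivariance(self, values, shift):
        x = np.array(values)
        base = iqr(x)
        assert iqr(np.random.default_rng(0).permutation(x)) == pytest.approx(base)
        assert iqr(x + shift) == pytest.approx(base, abs=1e-6)
        assert iqr(2 * x) == pytest.approx(2 * base, rel=1e-12, abs=1e-9)

    def test_extract_features_order_and_oracle(self):
        rng = np.random.default_rng(10)
        scores = {s: rng.normal(size=(20, 3)) for s in ("rest", "test", "recovery")}
        feats = extract_features(scores)
        assert feats.shape == (9,)
        # stage-major, component-minor; each cell equals a direct recomputation
        k = 0
        for stage in ("rest", "test", "recovery"):
            for j in range(3):
                assert feats[k] == pytest.approx(iqr(scores[stage][:, j]))
                k += 1

    def test_constant_scores_zero_vector(self):
        scores = {s: np.ones((5, 3)) for s in ("rest", "test", "recovery")}
        assert np.array_equal(extract_features(scores), np.zeros(9))

    def test_missing_stage_errors(self):
        with pytest.raises(ValueError, match="recovery"):
            extract_features({"rest": np.ones((5, 3)), "test": np.ones((5, 3))})


class TestLogistic:
    def test_separable_perfect_training_accuracy(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(6, 1, (20, 2))])
        y = np.array(["heart_failure"] * 20 + ["metabolic_syndrome"] * 20)
        clf = fit_logistic(X, y, C=1e6)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((4, 2)), ["heart_failure"] * 4)

    def test_matches_irls_oracle(self):
        """Coefficients on a 2-feature toy set match a hand-rolled
        iteratively-reweighted least-squares fit of the same (lightly
        penalized) likelihood within 1e-4."""
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(2, 1, (30, 2))])
        y01 = np.array([0] * 30 + [1] * 30)
        y = np.where(y01, "metabolic_syndrome", "heart_failure")
        C = 10.0
        clf = fit_logistic(X, y, C=C)

        # IRLS with the matching L2 penalty (lambda = 1/C, intercept free)
        Xd = np.hstack([X, np.ones((60, 1))])
        beta = np.zeros(3)
        lam = np.diag([1 / C, 1 / C, 0.0])
        for _ in range(100):
            eta = Xd @ beta
            p = 1 / (1 + np.exp(-eta))
            W = p * (1 - p)
            grad = Xd.T @ (y01 - p) - lam @ beta
            H = Xd.T @ (Xd * W[:, None]) + lam
            step = np.linalg.solve(H, grad)
            beta += step
            if np.max(np.abs(step)) < 1e-12:
                break
        assert np.allclose(clf.coef_.ravel(), beta[:2], atol=1e-4)
        assert np.allclose(clf.intercept_, beta[2], atol=1e-4)

    def test_probability_conventions(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(3, 1, (15, 2))])
        y = np.array(["heart_failure"] * 15 + ["metabolic_syndrome"] * 15)
        clf = fit_logistic(X, y)
        p = predict_heart_failure_probability(clf, X)
        assert np.all((0 < p) & (p < 1))
        assert p[:15].mean() > 0.5 > p[15:].mean()


class TestPipelines:
    def test_full_pipeline_deterministic(self, small_cohort):
        f1 = PCALogisticClassifier(random_state=5).fit(small_cohort)
        f2 = PCALogisticClassifier(random_state=5).fit(small_cohort)
        assert np.allclose(f1.features_, f2.features_, atol=0)
        assert np.array_equal(f1.predict(small_cohort), f2.predict(small_cohort))
        a1 = AutoencoderLogisticClassifier(random_state=5).fit(small_cohort)
        a2 = AutoencoderLogisticClassifier(random_state=5).fit(small_cohort)
        assert np.allclose(a1.features_, a2.features_, atol=0)

    def test_feature_vector_invariants(self, small_cohort):
        est = PCALogisticClassifier().fit(small_cohort)
        assert est.features_.shape == (len(small_cohort), 9)
        assert np.all(est.features_ >= 0)
        assert est.feature_names_[0] == "rest_c1_iqr"
        assert est.feature_names_[-1] == "recovery_c3_iqr"

    def test_pca_path_equals_injected_linear_orthonormal_encoder(self, small_cohort):
        """Consistency cross-check: an autoencoder whose encoder is the global
        PCA loading map yields the same per-stage IQR features as projecting
        with those loadings directly."""
        stats, transform = standardize_channels(small_cohort)
        pooled = np.vstack([transform(r) for r in small_cohort])
        pca_model = fit_stage_pca(pooled)  # global top-3 axes
        U = pca_model.components  # (3, 8), orthonormal rows
        zeros3, zeros8 = np.zeros(3), np.zeros(8)
        ae = AEModel(
            coefs=[U.T, np.eye(3), np.eye(3), U],
            intercepts=[-pca_model.mean @ U.T, zeros3, zeros3, zeros8],
            activation="identity",
        )
        for rec in small_cohort[:4]:
            stages = cd.segment_stages(rec.series)
            X_std = transform(rec)
            direct = extract_features(
                {s: pca_model.transform(X_std[stages.slices()[s]])
                 for s in ("rest", "test", "recovery")})
            via_ae = extract_features(
                {s: ae.encode(X_std)[stages.slices()[s]]
                 for s in ("rest", "test", "recovery")})
            assert np.allclose(direct, via_ae, atol=1e-3)

    def test_fitted_models_untouched_by_heldout_mutation(self, small_cohort):
        """No leakage: corrupting held-out records cannot change anything the
        training fold fitted."""
        train, held = small_cohort[:-2], small_cohort[-2:]
        est = PCALogisticClassifier(random_state=0).fit(train)
        coef_before = est.logistic_.coef_.copy()
        comps_before = {s: m.components.copy() for s, m in est.stage_pca_.items()}
        for rec in held:  # corrupt in place
            rec.series.data.loc[:, "vo2"] *= 100.0
        est.predict(held)
        assert np.array_equal(coef_before, est.logistic_.coef_)
        for s, m in est.stage_pca_.items():
            assert np.array_equal(comps_before[s], m.components)
        for rec in held:  # restore for other tests (session fixture)
            rec.series.data.loc[:, "vo2"] /= 100.0
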