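"""One-class boundary: decision-function oracles, ν selection, monotonicity."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.svm import OneClassSVM

from gaitshift.features import FeatureScores
from gaitshift.oneclass import (GaitBoundary, OcsvmParams, OutlierResult,
                                decision_function, kernel_sum, load_boundary,
                                save_boundary, score_cycles, train_boundary)
from gaitshift.pipeline import run_subject_quick
from gaitshift.synth import SynthSubjectConfig


def _tight_cloud(rng, n=300, k=5):
    return rng.standard_normal((n, k))


class TestDecisionFunction:
    def test_single_support_vector_at_zero_distance(self):
        sv = np.array([[1.0, 2.0, 3.0]])
        p = OcsvmParams(nu=0.5, kernel_scale=2.0, support_vectors=sv,
                        alphas=[1.0], rho=0.0)
        assert decision_function(p, sv[0]) == pytest.approx(1.0)

    def test_closed_form_at_distance_d(self):
        p = OcsvmParams(nu=0.5, kernel_scale=1.5, support_vectors=[[0.0, 0.0]],
                        alphas=[1.0], rho=0.3)
        x = np.array([3.0, 4.0])  # distance 5
        expected = np.exp(-25.0 / (2 * 1.5 ** 2)) - 0.3
        assert decision_function(p, x) == pytest.approx(expected, abs=1e-15)

    def test_matches_brute_force_summation(self, rng):
        sv = rng.normal(size=(17, 6))
        alphas = rng.uniform(0, 1, 17)
        p = OcsvmParams(nu=0.4, kernel_scale=1.3, support_vectors=sv,
                        alphas=alphas, rho=0.7)
        x = rng.normal(size=6)
        brute = sum(a * np.exp(-np.sum((s - x) ** 2) / (2 * 1.3 ** 2))
                    for a, s in zip(alphas, sv)) - 0.7
        assert decision_function(p, x) == pytest.approx(brute, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        p = OcsvmParams(nu=0.5, kernel_scale=1.0, support_vectors=[[0.0, 0.0]],
                        alphas=[1.0], rho=0.0)
        with pytest.raises(ValueError, match="dimension"):
            decision_function(p, np.zeros(3))


class TestAgainstQuadraticProgram:
    def test_fitted_boundary_matches_brute_force_dual(self, rng):
        """The extracted (support vectors, α, ρ) must reproduce the solution
        of the one-class dual QP solved by a generic optimizer."""
        Z = rng.standard_normal((30, 4))
        nu, scale, n = 0.3, 1.7, 30
        svm = OneClassSVM(kernel="rbf", gamma=1 / (2 * scale ** 2), nu=nu).fit(Z)
        params = OcsvmParams(nu=nu, kernel_scale=scale,
                             support_vectors=svm.support_vectors_,
                             alphas=svm.dual_coef_.ravel(),
                             rho=float(-svm.intercept_[0]))
        K = np.exp(-cdist(Z, Z, "sqeuclidean") / (2 * scale ** 2))
        res = minimize(lambda a: 0.5 * a @ K @ a, np.full(n, nu),
                       jac=lambda a: K @ a, bounds=[(0, 1)] * n,
                       constraints=[{"type": "eq",
                                     "fun": lambda a: a.sum() - nu * n,
                                     "jac": lambda a: np.ones(n)}],
                       method="SLSQP", options={"maxiter": 1000, "ftol": 1e-16})
        a = res.x
        free = (a > 1e-6) & (a < 1 - 1e-6)
        rho_qp = np.mean((K @ a)[free])
        X = rng.standard_normal((20, 4))
        Kt = np.exp(-cdist(X, Z, "sqeuclidean") / (2 * scale ** 2))
        np.testing.assert_allclose(decision_function(params, X),
                                   Kt @ a - rho_qp, atol=1e-2)


class TestTrainBoundary:
    def test_default_grid_achieves_under_one_percent_cv(self, rng):
        scores = FeatureScores(Z=_tight_cloud(rng), model_id=1)
        b = train_boundary(scores, random_state=3)
        assert b.cv_outlier_pct < 1.0
        assert 0.05 <= b.nu <= 0.95

    def test_far_field_points_are_all_outliers(self, rng):
        scores = FeatureScores(Z=_tight_cloud(rng), model_id=1)
        b = train_boundary(scores, random_state=3)
        far = FeatureScores(Z=_tight_cloud(rng) + 10.0, model_id=1)
        assert score_cycles(b, far).outlier_pct == 100.0

    def test_training_set_outlier_rate_bounded_by_nu(self, rng):
        # ν-property of the margin-offset formulation
        Z = _tight_cloud(rng)
        scores = FeatureScores(Z=Z, model_id=1)
        b = train_boundary(scores, nu_grid=[0.2], bias="margin",
                           cv_threshold_pct=101.0, random_state=0)
        res = score_cycles(b, scores)
        assert res.outlier_pct <= 0.2 * 100 + 2

    def test_calibrated_boundary_contains_all_training_cycles(self, rng):
        Z = _tight_cloud(rng)
        scores = FeatureScores(Z=Z, model_id=1)
        b = train_boundary(scores, random_state=3)
        assert score_cycles(b, scores).outlier_pct == 0.0

    def test_nu_monotone_training_outlier_fraction(self, rng):
        Z = _tight_cloud(rng, n=150)
        gamma = 1 / (2 * 2.0 ** 2)
        fracs = []
        for nu in [0.1, 0.3, 0.5, 0.7, 0.9]:
            svm = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu).fit(Z)
            p = OcsvmParams(nu=nu, kernel_scale=2.0,
                            support_vectors=svm.support_vectors_,
                            alphas=svm.dual_coef_.ravel(),
                            rho=float(-svm.intercept_[0]))
            fracs.append(np.mean(decision_function(p, Z) < 0))
        assert all(b >= a - 0.01 for a, b in zip(fracs, fracs[1:]))

    def test_no_qualifying_nu_reports_best_rate(self, rng):
        Z = _tight_cloud(rng, n=300)
        scores = FeatureScores(Z=Z, model_id=1)
        with pytest.raises(RuntimeError, match="best achieved"):
            train_boundary(scores, bias="margin", nu_grid=[0.5, 0.9],
                           random_state=0)

    def test_too_few_cycles_rejected(self, rng):
        scores = FeatureScores(Z=rng.standard_normal((10, 3)), model_id=1)
        with pytest.raises(ValueError, match="25"):
            train_boundary(scores)

    def test_feature_model_mismatch_rejected(self, rng):
        scores = FeatureScores(Z=_tight_cloud(rng), model_id=1)
        b = train_boundary(scores, random_state=3)
        alien = FeatureScores(Z=_tight_cloud(rng), model_id=2)
        with pytest.raises(ValueError, match="feature-model mismatch"):
            score_cycles(b, alien)

    def test_audit_trail_recorded(self, rng):
        scores = FeatureScores(Z=_tight_cloud(rng), model_id=1)
        b = train_boundary(scores, random_state=7)
        est = b.estimator
        assert est.split_seed_ == 7
        assert len(est.cv_rates_) == len(est.nu_grid_searched_) == 19


class TestPerturbationMonotonicity:
    def test_median_outlier_pct_nondecreasing_in_shift(self):
        """Core scientific property: larger injected post-intervention shifts
        yield larger outlier percentages (median over seeded replicates)."""
        deltas = [0.0, 0.1, 0.2, 0.3]
        medians = []
        for delta in deltas:
            outs = []
            for seed in range(10):
                cfg = SynthSubjectConfig(seed=500 + seed, shift_delta=delta)
                try:
                    outs.append(run_subject_quick(cfg)["post_outlier_pct"])
                except RuntimeError:
                    continue  # rare subjects never meet the <1% criterion
            medians.append(np.median(outs))
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0]


class TestPersistence:
    def test_save_load_preserves_decisions_to_1e9(self, tmp_path, rng):
        scores = FeatureScores(Z=_tight_cloud(rng), model_id=1)
        b = train_boundary(scores, random_state=3)
        save_boundary(b, tmp_path / "b")
        back = load_boundary(tmp_path / "b")
        X = rng.standard_normal((50, 5)) * 3
        np.testing.assert_allclose(back.estimator.decision_function(X),
                                   b.estimator.decision_function(X), atol=1e-9)
        assert back.feature_model_id == b.feature_model_id


class TestOutlierResult:
    def test_outlier_pct_definition(self):
        res = OutlierResult.from_decisions(np.array([1.0, -0.1, 0.0, -2.0]))
        assert res.outlier_pct == 50.0
        assert list(res.labels) == ["typical", "outlier", "typical", "outlier"]
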