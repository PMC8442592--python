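"""PCA, nested-CV ridge, and evaluation contracts."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge as SkRidge

import lscpm
from lscpm.exceptions import DataError, PreconditionError
from lscpm.predict import (
    CVConfig,
    FittedPipeline,
    RidgeFold,
    _solve_ridge,
    evaluate,
    fit_cv_ridge,
    fit_pca,
    fit_pipeline,
    predict_discovery,
    predict_external,
    predict_scores_external,
    project,
)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_of_100_subjects_yields_99_components():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((100, 500))
    pca = fit_pca(x, "max")
    assert pca.n_components == 99
    assert np.all(pca.explained_variance > 0)
    # components ordered by decreasing explained variance
    assert np.all(np.diff(pca.explained_variance) <= 1e-12)


def test_pca_identical_rows_zero_components():
    x = np.tile(np.arange(10.0), (6, 1))
    with pytest.warns(UserWarning, match="rank"):
        pca = fit_pca(x, "max")
    assert pca.n_components == 0


def test_pca_loadings_orthonormal_and_scores_decorrelated():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((30, 12))
    pca = fit_pca(x)
    np.testing.assert_allclose(
        pca.transform.T @ pca.transform, np.eye(pca.n_components), atol=1e-8
    )
    s = project(pca, x)
    cov = np.cov(s, rowvar=False)
    np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)
    np.testing.assert_allclose(np.diag(cov), pca.explained_variance, atol=1e-8)


def test_pca_sign_convention():
    rng = np.random.default_rng(2)
    pca = fit_pca(rng.standard_normal((20, 8)))
    peak = pca.transform[np.abs(pca.transform).argmax(axis=0),
                         np.arange(pca.n_components)]
    assert np.all(peak > 0)


def test_pca_matches_sklearn_subspace():
    from sklearn.decomposition import PCA as SkPCA

    rng = np.random.default_rng(3)
    x = rng.standard_normal((25, 10))
    ours = fit_pca(x, 5)
    ref = SkPCA(n_components=5).fit(x)
    np.testing.assert_allclose(
        ours.explained_variance, ref.explained_variance_, atol=1e-10
    )
    np.testing.assert_allclose(
        np.abs(ours.transform), np.abs(ref.components_.T), atol=1e-8
    )


def test_project_centers_training_scores():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((20, 6)) + 5.0
    pca = fit_pca(x)
    np.testing.assert_allclose(project(pca, x).mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(project(pca, pca.center), 0.0, atol=1e-10)


def test_project_uses_discovery_center_not_validation_mean():
    rng = np.random.default_rng(5)
    x = rng.standard_normal((20, 6))
    pca = fit_pca(x)
    shifted = rng.standard_normal((15, 6)) + 10.0
    scores = project(pca, shifted)
    expected_mean = (shifted.mean(axis=0) - pca.center) @ pca.transform
    np.testing.assert_allclose(scores.mean(axis=0), expected_mean, atol=1e-8)
    assert np.abs(expected_mean).max() > 1.0  # the shift survives projection


def test_project_rejects_column_mismatch():
    pca = fit_pca(np.random.default_rng(0).standard_normal((10, 6)))
    with pytest.raises(DataError):
        project(pca, np.zeros((3, 5)))


# ---------------------------------------------------------------------------
# Ridge solver
# ---------------------------------------------------------------------------

def test_ridge_closed_form_toy():
    s = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, -1.0], [0.5, 0.5]])
    y = np.array([1.0, 2.0, 3.0, 0.5, 1.5])
    lam = 0.7
    beta, intercept = _solve_ridge(s, y, lam)
    # independent closed form: beta = (Sc'Sc + lam I)^-1 Sc'yc
    sc = s - s.mean(axis=0)
    yc = y - y.mean()
    expected = np.linalg.inv(sc.T @ sc + lam * np.eye(2)) @ sc.T @ yc
    np.testing.assert_allclose(beta, expected, atol=1e-12)
    np.testing.assert_allclose(intercept, y.mean() - beta @ s.mean(axis=0), atol=1e-12)


def test_ridge_matches_sklearn():
    rng = np.random.default_rng(6)
    s = rng.standard_normal((40, 7))
    y = rng.standard_normal(40)
    for lam in (1e-3, 1.0, 50.0):
        beta, intercept = _solve_ridge(s, y, lam)
        ref = SkRidge(alpha=lam, fit_intercept=True).fit(s, y)
        np.testing.assert_allclose(beta, ref.coef_, atol=1e-8)
        np.testing.assert_allclose(intercept, ref.intercept_, atol=1e-8)


def test_ridge_zero_penalty_equals_ols():
    rng = np.random.default_rng(7)
    s = rng.standard_normal((30, 4))
    y = rng.standard_normal(30)
    beta, intercept = _solve_ridge(s, y, 0.0)
    design = np.column_stack([np.ones(30), s])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    np.testing.assert_allclose(beta, coef[1:], atol=1e-6)
    np.testing.assert_allclose(intercept, coef[0], atol=1e-6)


def test_ridge_infinite_penalty_shrinks_to_mean():
    rng = np.random.default_rng(8)
    s = rng.standard_normal((30, 4))
    y = rng.standard_normal(30) + 3.0
    beta, intercept = _solve_ridge(s, y, 1e12)
    assert np.abs(beta).max() < 1e-9
    np.testing.assert_allclose(intercept, y.mean(), atol=1e-6)


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------

def test_cv_folds_partition_cohort():
    rng = np.random.default_rng(9)
    s = rng.standard_normal((35, 6))
    y = rng.standard_normal(35)
    pipe = fit_cv_ridge(s, y, CVConfig(n_folds=5, inner_folds=3, seed=1))
    folds = pipe.repeats[0]
    all_test = np.concatenate([f.test_idx for f in folds])
    assert sorted(all_test) == list(range(35))
    sizes = [f.test_idx.size for f in folds]
    assert max(sizes) - min(sizes) <= 1
    for f in folds:
        assert f.lam in pipe.config.lambda_grid
        assert not set(f.test_idx) & set(f.train_idx)


def test_no_leakage_from_test_fold():
    """Perturbing a fold's test-set y never changes that fold's model."""
    rng = np.random.default_rng(10)
    s = rng.standard_normal((40, 5))
    y = rng.standard_normal(40)
    cfg = CVConfig(n_folds=4, inner_folds=3, seed=2)
    pipe1 = fit_cv_ridge(s, y, cfg)
    fold0 = pipe1.repeats[0][0]
    y_mod = y.copy()
    y_mod[fold0.test_idx] += rng.standard_normal(fold0.test_idx.size) * 10
    pipe2 = fit_cv_ridge(s, y_mod, cfg)
    fold0_mod = pipe2.repeats[0][0]
    np.testing.assert_array_equal(fold0.test_idx, fold0_mod.test_idx)
    np.testing.assert_allclose(fold0.coefficients, fold0_mod.coefficients, atol=1e-12)
    assert fold0.lam == fold0_mod.lam


def test_loo_reduction_allowed():
    rng = np.random.default_rng(11)
    s = rng.standard_normal((8, 3))
    y = rng.standard_normal(8)
    pipe = fit_cv_ridge(s, y, CVConfig(n_folds=8, inner_folds=3, seed=0))
    preds = predict_discovery(pipe, s)
    assert preds.shape == (8,)
    assert all(f.test_idx.size == 1 for f in pipe.repeats[0])


def test_too_few_subjects_rejected():
    rng = np.random.default_rng(12)
    with pytest.raises(PreconditionError):
        fit_cv_ridge(rng.standard_normal((15, 3)), rng.standard_normal(15),
                     CVConfig(n_folds=10))


def test_nan_in_y_rejected():
    rng = np.random.default_rng(13)
    y = rng.standard_normal(30)
    y[4] = np.nan
    with pytest.raises(DataError):
        fit_cv_ridge(rng.standard_normal((30, 3)), y, CVConfig(n_folds=3))


def test_constant_y_predicts_constant():
    rng = np.random.default_rng(14)
    s = rng.standard_normal((24, 4))
    y = np.full(24, 7.5)
    pipe = fit_cv_ridge(s, y, CVConfig(n_folds=4, inner_folds=3, seed=0))
    np.testing.assert_allclose(predict_discovery(pipe, s), 7.5, atol=1e-8)


def test_huge_penalty_grid_predicts_training_mean():
    rng = np.random.default_rng(15)
    s = rng.standard_normal((24, 4))
    y = rng.standard_normal(24)
    pipe = fit_cv_ridge(
        s, y, CVConfig(n_folds=4, inner_folds=3, lambda_grid=[1e12], seed=0)
    )
    preds = predict_discovery(pipe, s)
    for f in pipe.repeats[0]:
        np.testing.assert_allclose(
            preds[f.test_idx], y[f.train_idx].mean(), atol=1e-6
        )


# ---------------------------------------------------------------------------
# External prediction
# ---------------------------------------------------------------------------

def _manual_pipeline(folds, pca=None):
    cfg = CVConfig(n_folds=max(2, len(folds)), inner_folds=2)
    return FittedPipeline(pca=pca, repeats=[folds], config=cfg, n_subjects=10)


def test_identical_folds_average_equals_single_model():
    beta = np.array([1.0, -2.0])
    fold = RidgeFold(beta, 0.5, 1.0, np.arange(5), np.arange(5, 10))
    pipe = _manual_pipeline([fold, fold, fold])
    s = np.random.default_rng(16).standard_normal((6, 2))
    np.testing.assert_allclose(
        predict_scores_external(pipe, s), 0.5 + s @ beta, atol=1e-12
    )


def test_averaging_is_linear_in_coefficients():
    rng = np.random.default_rng(17)
    folds = [
        RidgeFold(rng.standard_normal(3), float(rng.standard_normal()), 1.0,
                  np.arange(5), np.arange(5, 10))
        for _ in range(4)
    ]
    pipe = _manual_pipeline(folds)
    s = rng.standard_normal((7, 3))
    mean_beta = np.mean([f.coefficients for f in folds], axis=0)
    mean_b = np.mean([f.intercept for f in folds])
    np.testing.assert_allclose(
        predict_scores_external(pipe, s), mean_b + s @ mean_beta, atol=1e-12
    )


def test_external_generalization_on_shared_truth():
    """Discovery and validation halves share the planted edges, so the
    averaged fold models transfer with positive r."""
    spec = lscpm.CohortSpec(
        n_subjects=90, n_rois=15, n_signal_edges=10, effect_size=1.0,
        edge_noise_sd=0.5, seed=21,
    )
    fm, ls, _ = lscpm.generate_edge_cohort(spec)
    x_disc, x_val = fm.values[:60], fm.values[60:]
    y_disc, y_val = ls[:60], ls[60:]
    pipe = fit_pipeline(x_disc, y_disc, config=CVConfig(n_folds=5, inner_folds=3, seed=0))
    r_val, n = evaluate(predict_external(pipe, x_val), y_val)
    assert n == 30
    assert r_val > 0.3


def test_oof_r_increases_with_effect_size():
    means = []
    for effect in (0.0, 0.4, 0.8):
        rs = []
        for rep in range(4):
            spec = lscpm.CohortSpec(
                n_subjects=80, n_rois=20, n_signal_edges=10,
                effect_size=effect, edge_noise_sd=1.0, seed=500 + rep,
            )
            fm, ls, _ = lscpm.generate_edge_cohort(spec)
            pipe = fit_pipeline(fm, ls, config=CVConfig(seed=rep))
            rs.append(evaluate(predict_discovery(pipe, project(pipe.pca, fm)), ls)[0])
        means.append(np.mean(rs))
    assert means[0] < means[1] < means[2]
    assert means[2] > 0.5


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def test_evaluate_perfect_and_anti_correlation():
    y = np.array([1.0, 2.0, 4.0, 8.0])
    assert evaluate(y, y)[0] == pytest.approx(1.0)
    assert evaluate(-y, y)[0] == pytest.approx(-1.0)


def test_evaluate_hand_computed_four_points():
    pred = np.array([1.0, 2.0, 3.0, 5.0])
    actual = np.array([2.0, 1.0, 4.0, 6.0])
    # manual product-moment formula
    pc, ac = pred - pred.mean(), actual - actual.mean()
    expected = (pc @ ac) / np.sqrt((pc @ pc) * (ac @ ac))
    r, n = evaluate(pred, actual)
    assert n == 4
    assert r == pytest.approx(expected, abs=1e-12)


def test_evaluate_constant_vector_rejected():
    with pytest.raises(DataError):
        evaluate(np.ones(5), np.arange(5.0))


def test_evaluate_too_short_rejected():
    with pytest.raises(PreconditionError):
        evaluate(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
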