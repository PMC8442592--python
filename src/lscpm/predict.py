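"""PCA dimensionality reduction and ridge regression with nested 10-fold CV.

The modeling stage follows the standard connectome-based predictive modeling
recipe: PCA is fit once on the full discovery feature matrix (an unsupervised
step, so trait labels never enter it), the discovery cohort is split into k
outer folds, and for each outer fold a ridge model is trained on the k-1
remaining folds with the penalty chosen by an inner cross-validation that
never sees the outer test fold.  Discovery performance is the Pearson r
between each subject's single out-of-fold prediction and the actual score;
external validation projects a held-out cohort through the *discovery* PCA
and averages the k fold models' predictions.

The ridge objective is ``sum_i (y_i - b - beta' s_i)^2 + lambda ||beta||^2``
with an unpenalized intercept.  The solver eigendecomposes the training Gram
matrix once per fold and reuses it across the whole lambda grid, which keeps
permutation-test refits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import FeatureMatrix
from .exceptions import DataError, ParameterError, PreconditionError


def default_lambda_grid() -> np.ndarray:
    """13 log-spaced ridge penalties from 1e-3 to 1e3."""
    return np.logspace(-3.0, 3.0, 13)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Centered PCA: ``scores = (X - center) @ transform``.

    ``transform`` is E x K with orthonormal columns ordered by decreasing
    explained variance; the sign of each column is fixed so that its
    largest-magnitude loading is positive.
    """

    center: np.ndarray
    transform: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.transform.shape[1]


@dataclass
class RidgeFold:
    """One outer fold's ridge model and its train/test split."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVConfig:
    """Cross-validation settings: outer/inner fold counts, penalty grid, seed."""

    n_folds: int = 10
    inner_folds: int = 5
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    seed: int = 0
    n_repeats: int = 1  # >1 averages out-of-fold predictions over repeats

    def __post_init__(self) -> None:
        self.lambda_grid = np.sort(np.asarray(self.lambda_grid, dtype=float))
        if self.lambda_grid.size == 0 or np.any(self.lambda_grid < 0):
            raise ParameterError("lambda_grid must be non-empty and non-negative")
        if self.n_folds < 2 or self.inner_folds < 2:
            raise ParameterError("n_folds and inner_folds must be >= 2")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")


@dataclass
class FittedPipeline:
    """A discovery fit: one shared PCA plus k ridge fold models per repeat."""

    pca: PCAModel | None
    repeats: list[list[RidgeFold]]
    config: CVConfig
    n_subjects: int

    @property
    def folds(self) -> list[RidgeFold]:
        """All fold models, repeats concatenated (k models in the default
        single-repeat mode)."""
        return [f for rep in self.repeats for f in rep]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

_VARIANCE_RTOL = 1e-12


def fit_pca(X: FeatureMatrix | np.ndarray, n_components: int | str = "max") -> PCAModel:
    """Centered PCA of the feature matrix via SVD.

    ``n_components="max"`` resolves to ``min(n - 1, E)``.  Components whose
    explained variance is numerically zero (relative to the largest) are
    dropped, with a warning if that truncates below the request.
    """
    x = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, e = x.shape
    if n < 2:
        raise PreconditionError("PCA needs at least 2 subjects")
    k_max = min(n - 1, e)
    if n_components == "max":
        k = k_max
    else:
        k = int(n_components)
        if k < 1:
            raise ParameterError("n_components must be >= 1")
        k = min(k, k_max)
    center = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - center, full_matrices=False)
    var = s**2 / (n - 1)
    nonzero = var > _VARIANCE_RTOL * max(var[0], 1e-300) if var.size else var > 0
    rank = int(nonzero.sum())
    if rank < k:
        import warnings

        warnings.warn(
            f"requested {k} components but data rank is {rank}; truncating",
            stacklevel=2,
        )
        k = rank
    transform = vt[:k].T
    # sign convention: largest-magnitude loading of each component positive
    if k:
        flip = np.sign(transform[np.abs(transform).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        transform = transform * flip
    return PCAModel(center=center, transform=transform, explained_variance=var[:k])


def project(pca: PCAModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project features onto the PCA basis: ``(X - center) @ transform``.

    No refitting happens here — validation cohorts are centered with the
    *discovery* mean, by construction.
    """
    x = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != pca.center.shape[0]:
        raise DataError(
            f"feature dimension {x.shape[1]} does not match PCA ({pca.center.shape[0]})"
        )
    return (x - pca.center) @ pca.transform


# ---------------------------------------------------------------------------
# Ridge with nested CV
# ---------------------------------------------------------------------------

def _solve_ridge(
    s: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Closed-form ridge with unpenalized intercept (single lambda)."""
    s_mean = s.mean(axis=0)
    y_mean = y.mean()
    sc = s - s_mean
    yc = y - y_mean
    k = s.shape[1]
    beta = np.linalg.solve(sc.T @ sc + lam * np.eye(k), sc.T @ yc)
    return beta, float(y_mean - beta @ s_mean)


def _ridge_grid_eigh(
    sc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Centered ridge coefficients for every lambda at once.

    Eigendecomposes ``S'S = Q diag(w) Q'`` once, then
    ``beta(lam) = Q diag(1/(w + lam)) Q' S'y`` for the whole grid.
    Returns an (n_lambda, K) array.
    """
    gram = sc.T @ sc
    w, q = np.linalg.eigh(gram)
    w = np.clip(w, 0.0, None)  # guard tiny negative eigenvalues
    qty = q.T @ (sc.T @ yc)
    denom = w[None, :] + lambdas[:, None]  # (L, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(denom > 0, qty[None, :] / denom, 0.0)
    return scaled @ q.T


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded uniform shuffle into k folds with sizes differing by <= 1."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _choose_lambda(
    s_train: np.ndarray,
    y_train: np.ndarray,
    lambdas: np.ndarray,
    inner_folds: int,
    rng: np.random.Generator,
) -> float:
    """Inner-CV mean squared error over the grid; ties break to larger lambda."""
    n = s_train.shape[0]
    folds = _fold_indices(n, min(inner_folds, n), rng)
    sse = np.zeros(lambdas.size)
    for test in folds:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        s_tr, y_tr = s_train[mask], y_train[mask]
        s_mean, y_mean = s_tr.mean(axis=0), y_tr.mean()
        betas = _ridge_grid_eigh(s_tr - s_mean, y_tr - y_mean, lambdas)  # (L, K)
        preds = (s_train[test] - s_mean) @ betas.T + y_mean  # (n_test, L)
        sse += ((preds - y_train[test][:, None]) ** 2).sum(axis=0)
    best = sse.min()
    # ties (within float tolerance) resolved toward more regularization
    candidates = np.nonzero(sse <= best * (1 + 1e-12))[0]
    return float(lambdas[candidates.max()])


def fit_cv_ridge(
    scores: np.ndarray, y: np.ndarray, config: CVConfig | None = None
) -> FittedPipeline:
    """Nested cross-validated ridge on PC scores.

    Outer folds come from a seeded shuffle; per outer fold the penalty is
    chosen by inner CV on the training folds only (minimizing MSE), then the
    fold model is refit on all training folds at that penalty.
    """
    cfg = config or CVConfig()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n = scores.shape[0]
    if y.shape != (n,):
        raise DataError("y must be one score per subject")
    if np.any(~np.isfinite(y)):
        raise DataError("NaN or infinite value in y")
    if n < 2 * cfg.n_folds and cfg.n_folds != n:
        # k == n is the leave-one-out reduction and is explicitly allowed
        raise PreconditionError(
            f"need n >= 2k subjects for {cfg.n_folds}-fold CV (n={n}), "
            "or k == n for leave-one-out"
        )
    rng = np.random.default_rng(cfg.seed)
    repeats: list[list[RidgeFold]] = []
    for _ in range(cfg.n_repeats):
        folds: list[RidgeFold] = []
        for test_idx in _fold_indices(n, cfg.n_folds, rng):
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            train_idx = np.nonzero(mask)[0]
            s_tr, y_tr = scores[train_idx], y[train_idx]
            lam = _choose_lambda(s_tr, y_tr, cfg.lambda_grid, cfg.inner_folds, rng)
            beta, intercept = _solve_ridge(s_tr, y_tr, lam)
            folds.append(
                RidgeFold(
                    coefficients=beta,
                    intercept=intercept,
                    lam=lam,
                    train_idx=train_idx,
                    test_idx=test_idx,
                )
            )
        repeats.append(folds)
    return FittedPipeline(pca=None, repeats=repeats, config=cfg, n_subjects=n)


def fit_pipeline(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    n_components: int | str = "max",
    config: CVConfig | None = None,
) -> FittedPipeline:
    """Convenience wrapper: fit PCA on X, project, then nested-CV ridge."""
    pca = fit_pca(X, n_components)
    pipeline = fit_cv_ridge(project(pca, X), y, config)
    pipeline.pca = pca
    return pipeline


def predict_discovery(pipeline: FittedPipeline, scores: np.ndarray) -> np.ndarray:
    """Out-of-fold predictions: each subject predicted by the one fold model
    not trained on it (averaged across repeats if n_repeats > 1)."""
    scores = np.asarray(scores, dtype=float)
    n = pipeline.n_subjects
    if scores.shape[0] != n:
        raise DataError("scores row count does not match the fitted cohort")
    preds = np.zeros(n)
    for folds in pipeline.repeats:
        covered = np.zeros(n, dtype=bool)
        for f in folds:
            preds[f.test_idx] += f.intercept + scores[f.test_idx] @ f.coefficients
            covered[f.test_idx] = True
        if not covered.all():
            raise RuntimeError("fold test sets do not partition the cohort")
    return preds / len(pipeline.repeats)


def predict_scores_external(pipeline: FittedPipeline, scores: np.ndarray) -> np.ndarray:
    """Average the fold models' predictions for already-projected scores."""
    scores = np.asarray(scores, dtype=float)
    folds = pipeline.folds
    preds = np.zeros(scores.shape[0])
    for f in folds:
        preds += f.intercept + scores @ f.coefficients
    return preds / len(folds)


def predict_external(
    pipeline: FittedPipeline, X_val: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Project a validation cohort through the discovery PCA and average the
    k fold models' predictions."""
    if pipeline.pca is None:
        raise DataError("pipeline has no PCA model; fit with fit_pipeline")
    return predict_scores_external(pipeline, project(pipeline.pca, X_val))


def evaluate(pred: np.ndarray, actual: np.ndarray) -> tuple[float, int]:
    """Pearson correlation between predicted and actual scores, with n."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise DataError("pred and actual must be equal-length vectors")
    n = pred.shape[0]
    if n < 3:
        raise PreconditionError("need at least 3 pairs for a correlation")
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        raise DataError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(pred, actual).statistic)
    return r, n
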