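"""Permutation significance for the predicted-vs-actual correlation.

The null hypothesis is that functional connectivity carries no information
about the trait.  Each iteration shuffles the discovery trait scores,
re-runs the full cross-validated ridge fit on the (unchanged) PC scores, and
records the resulting predicted-vs-actual correlation.  PCA itself is not
refit: it is unsupervised, so a shuffle of y cannot change it — reusing it is
an exactness-preserving optimization, not an approximation.

The p-value uses the add-one estimator ``p = (1 + #{r_null >= r_obs}) /
(1 + n_perm)``, one-sided toward positive predictability by default, which is
bounded away from zero at ``1/(1 + n_perm)``.

Per-iteration seeds are derived from the master seed up front, so results do
not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .predict import (
    CVConfig,
    evaluate,
    fit_cv_ridge,
    predict_discovery,
    predict_scores_external,
)


@dataclass
class PermutationResult:
    """Observed r, its permutation null distribution, and the p-value."""

    observed_r: float
    null_r: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    two_sided: bool = False


def _iteration_seeds(seed: int, n_perm: int) -> np.ndarray:
    """Independent per-iteration seeds (all < 2**31) from the master seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_perm, dtype=np.uint32).astype(np.int64) % (2**31)


def _safe_r(pred: np.ndarray, actual: np.ndarray) -> float:
    """Pearson r, with constant predictions mapped to r = 0 (no linear
    association) so degenerate null fits cannot abort a permutation run."""
    if np.ptp(pred) == 0:
        return 0.0
    return evaluate(pred, actual)[0]


def _p_value(observed: float, null_r: np.ndarray, two_sided: bool) -> float:
    if two_sided:
        exceed = int(np.sum(np.abs(null_r) >= abs(observed)))
    else:
        exceed = int(np.sum(null_r >= observed))
    return (1 + exceed) / (1 + null_r.size)


def permute_discovery(
    scores: np.ndarray,
    y: np.ndarray,
    config: CVConfig | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    two_sided: bool = False,
) -> PermutationResult:
    """Permutation test of the discovery out-of-fold correlation.

    Each iteration shuffles y, re-draws CV folds, refits the nested-CV ridge
    on the fixed PC scores, and correlates out-of-fold predictions with the
    *shuffled* scores, yielding one null r.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    cfg = config or CVConfig()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)

    pipeline = fit_cv_ridge(scores, y, cfg)
    observed_r = _safe_r(predict_discovery(pipeline, scores), y)

    iter_seeds = _iteration_seeds(seed, n_perm)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(iter_seeds[i])
        y_perm = y[rng.permutation(y.size)]
        cfg_i = CVConfig(
            n_folds=cfg.n_folds,
            inner_folds=cfg.inner_folds,
            lambda_grid=cfg.lambda_grid,
            seed=int(iter_seeds[i]),
            n_repeats=cfg.n_repeats,
        )
        null_pipe = fit_cv_ridge(scores, y_perm, cfg_i)
        null_r[i] = _safe_r(predict_discovery(null_pipe, scores), y_perm)

    return PermutationResult(
        observed_r=observed_r,
        null_r=null_r,
        p_value=_p_value(observed_r, null_r, two_sided),
        n_perm=n_perm,
        seed=seed,
        two_sided=two_sided,
    )


def permute_validation(
    scores_disc: np.ndarray,
    y_disc: np.ndarray,
    scores_val: np.ndarray,
    y_val: np.ndarray,
    config: CVConfig | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    two_sided: bool = False,
) -> PermutationResult:
    """Permutation test of the external-validation correlation.

    Each iteration trains the k fold models on shuffled discovery scores,
    applies them (averaged) to the already-projected validation scores, and
    correlates with the actual validation scores, yielding one null r.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    cfg = config or CVConfig()
    scores_disc = np.asarray(scores_disc, dtype=float)
    scores_val = np.asarray(scores_val, dtype=float)
    y_disc = np.asarray(y_disc, dtype=float)
    y_val = np.asarray(y_val, dtype=float)

    pipeline = fit_cv_ridge(scores_disc, y_disc, cfg)
    observed_r = _safe_r(predict_scores_external(pipeline, scores_val), y_val)

    iter_seeds = _iteration_seeds(seed, n_perm)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(iter_seeds[i])
        y_perm = y_disc[rng.permutation(y_disc.size)]
        cfg_i = CVConfig(
            n_folds=cfg.n_folds,
            inner_folds=cfg.inner_folds,
            lambda_grid=cfg.lambda_grid,
            seed=int(iter_seeds[i]),
            n_repeats=cfg.n_repeats,
        )
        null_pipe = fit_cv_ridge(scores_disc, y_perm, cfg_i)
        null_r[i] = _safe_r(predict_scores_external(null_pipe, scores_val), y_val)

    return PermutationResult(
        observed_r=observed_r,
        null_r=null_r,
        p_value=_p_value(observed_r, null_r, two_sided),
        n_perm=n_perm,
        seed=seed,
        two_sided=two_sided,
    )
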