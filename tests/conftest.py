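import numpy as np
import pytest

import lscpm
from lscpm.predict import CVConfig, fit_pca, fit_cv_ridge, project


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """Edge-mode cohort with a strong planted signal (n=60, R=12)."""
    spec = lscpm.CohortSpec(
        n_subjects=60, n_rois=12, n_signal_edges=8, effect_size=1.0,
        edge_noise_sd=0.5, seed=7,
    )
    fm, ls, signal_edges = lscpm.generate_edge_cohort(spec)
    return fm, ls, signal_edges


@pytest.fixture(scope="session")
def fitted_pipeline(small_signal_cohort):
    """A small fitted PCA + nested-CV ridge pipeline (5 folds)."""
    fm, ls, _ = small_signal_cohort
    pca = fit_pca(fm)
    scores = project(pca, fm)
    pipe = fit_cv_ridge(scores, ls, CVConfig(n_folds=5, inner_folds=3, seed=0))
    pipe.pca = pca
    return pipe, fm, ls
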