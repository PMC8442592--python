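"""Synthetic cohorts with planted trait-coupled connectivity.

Two generation modes emulate the statistical structure the downstream
analysis assumes, at two levels of realism:

``generate_edge_cohort``
    draws Fisher-z edge values directly: ``z_ie = mu_e + gamma_e *
    (LS_i - mean)/sd + eps_ie`` with baseline means ``mu_e ~ N(0.2, 0.1)``
    (a typical empirical functional-connectivity range in z units), slope
    ``gamma_e = effect_size`` at the planted signal edges and 0 elsewhere,
    and i.i.d. Gaussian noise.  This is the fast path for calibration and
    recovery studies.

``generate_timeseries_cohort``
    draws ROI time series from a shared-latent-source factor model in which
    the pairwise coupling at the planted edges increases with standardized
    trait score, then adds smooth tissue nuisance signals, random-walk head
    motion with injected spikes large enough to guarantee FD > 0.5 mm, and
    broadband artifacts at spike frames — exercising the full preprocessing
    chain.

Both modes are deterministic given the spec's seed.  Trait scores default to
the study cohort's life-satisfaction distribution (54.5 +/- 9.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import (
    FeatureMatrix,
    SubjectRecord,
    edge_pairs,
    n_edges,
)
from .exceptions import ParameterError, PreconditionError

N_NUISANCE_REGRESSORS = 20

# factor-model coupling: target edge correlation at a planted edge is
# clip(BASE + SLOPE * effect_size * z_LS, ...) so effect_size is the
# per-SD change in coupling strength
_BASE_COUPLING = 0.30
_COUPLING_SLOPE = 0.15
_TISSUE_MIX_SD = 0.15
_SPIKE_ARTIFACT_SD = 6.0
_FAMILY_MU_SD = 0.1
_FAMILY_NOISE_CORR = 0.5


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults follow the study cohort."""

    n_subjects: int = 100
    n_rois: int = 427
    n_timepoints: int = 1200
    tr_seconds: float = 0.72
    ls_mean: float = 54.5
    ls_sd: float = 9.0
    n_signal_edges: int = 30
    effect_size: float = 0.5
    edge_noise_sd: float = 1.0
    motion_spike_rate: float = 0.0
    family_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.n_rois < 2:
            raise ParameterError("n_rois must be >= 2")
        if self.ls_sd <= 0:
            raise ParameterError("ls_sd must be positive")
        if self.edge_noise_sd <= 0:
            raise ParameterError("edge_noise_sd must be positive")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        e = n_edges(self.n_rois)
        if not 0 <= self.n_signal_edges <= e:
            raise ParameterError(
                f"n_signal_edges must be in [0, {e}] for R={self.n_rois}"
            )
        if not 0.0 <= self.motion_spike_rate <= 1.0:
            raise ParameterError("motion_spike_rate must be a probability")
        if self.family_pairs < 0 or 2 * self.family_pairs > self.n_subjects:
            raise ParameterError(
                "family_pairs must satisfy 2 * family_pairs <= n_subjects"
            )

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_rois)


@dataclass
class SyntheticCohort:
    """A generated time-series cohort plus its ground truth."""

    subjects: list[SubjectRecord]
    true_signal_edges: np.ndarray
    true_effects: np.ndarray
    ls_scores: np.ndarray
    spec: CohortSpec = field(repr=False, default=None)


def _draw_ls(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    return spec.ls_mean + spec.ls_sd * rng.standard_normal(spec.n_subjects)


def _draw_signal_edges(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    return np.sort(
        rng.choice(spec.n_edges, size=spec.n_signal_edges, replace=False)
    )


def generate_edge_cohort(
    spec: CohortSpec,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Draw a cohort directly in edge space.

    Returns ``(features, ls_scores, true_signal_edges)``.  Feature value for
    subject i at edge e is ``mu_e + gamma_e * (LS_i - ls_mean)/ls_sd +
    eps_ie`` with ``gamma_e = effect_size`` at signal edges, 0 elsewhere, and
    ``eps ~ N(0, edge_noise_sd)``.
    """
    rng = np.random.default_rng(spec.seed)
    e = spec.n_edges
    ls = _draw_ls(spec, rng)
    signal_edges = _draw_signal_edges(spec, rng)
    mu = rng.normal(0.2, 0.1, size=e)
    gamma = np.zeros(e)
    gamma[signal_edges] = spec.effect_size
    z_ls = (ls - spec.ls_mean) / spec.ls_sd

    eps = rng.standard_normal((spec.n_subjects, e)) * spec.edge_noise_sd
    values = mu[None, :] + np.outer(z_ls, gamma) + eps

    # sibling pairs (0,1), (2,3), ...: shared baseline offset plus
    # within-pair noise correlation
    if spec.family_pairs:
        rho = _FAMILY_NOISE_CORR
        for p in range(spec.family_pairs):
            a, b = 2 * p, 2 * p + 1
            delta = rng.normal(0.0, _FAMILY_MU_SD, size=e)
            shared = rng.standard_normal(e) * spec.edge_noise_sd
            for s in (a, b):
                fresh = rng.standard_normal(e) * spec.edge_noise_sd
                values[s] = (
                    mu
                    + delta
                    + gamma * z_ls[s]
                    + np.sqrt(rho) * shared
                    + np.sqrt(1 - rho) * fresh
                )

    fm = FeatureMatrix(
        values=values,
        n_rois=spec.n_rois,
        subject_ids=tuple(f"sub-{i:04d}" for i in range(spec.n_subjects)),
    )
    return fm, ls, signal_edges


def _smooth_noise(
    rng: np.random.Generator, t: int, n_cols: int, window: int = 15
) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise, unit-ish variance."""
    raw = rng.standard_normal((t + window, n_cols))
    kernel = np.ones(window) / window
    out = np.empty((t, n_cols))
    for c in range(n_cols):
        out[:, c] = np.convolve(raw[:, c], kernel, mode="valid")[:t]
    return out * np.sqrt(window)


def generate_timeseries_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full time-series cohort through the factor model.

    Planted edges (i, j) receive a shared latent source whose loading grows
    with the subject's standardized trait score, so the post-preprocessing
    Fisher-z at those edges correlates with the trait.  Motion parameters are
    smooth random walks; at Bernoulli(``motion_spike_rate``) frames a
    translation jump drawn Uniform(0.6, 1.5) mm is injected (guaranteeing
    FD > 0.5 mm) together with a broadband artifact across all ROIs.
    """
    if spec.n_timepoints < 4 * N_NUISANCE_REGRESSORS:
        raise PreconditionError(
            f"n_timepoints must be >= {4 * N_NUISANCE_REGRESSORS} "
            f"(4 x number of nuisance regressors), got {spec.n_timepoints}"
        )
    rng = np.random.default_rng(spec.seed)
    t, r = spec.n_timepoints, spec.n_rois
    ls = _draw_ls(spec, rng)
    signal_edges = _draw_signal_edges(spec, rng)
    rows, cols = edge_pairs(r)
    edge_i, edge_j = rows[signal_edges], cols[signal_edges]
    z_ls = (ls - spec.ls_mean) / spec.ls_sd

    # per-subject baseline coupling offsets; siblings share theirs
    offsets = rng.normal(0.0, 0.05, size=(spec.n_subjects, spec.n_signal_edges))
    for p in range(spec.family_pairs):
        offsets[2 * p + 1] = offsets[2 * p]

    subjects: list[SubjectRecord] = []
    for s in range(spec.n_subjects):
        x = rng.standard_normal((t, r))
        rho = np.clip(
            _BASE_COUPLING
            + offsets[s]
            + _COUPLING_SLOPE * spec.effect_size * z_ls[s],
            0.02,
            0.9,
        )
        loading = np.sqrt(rho / (1.0 - rho))
        latent = rng.standard_normal((t, spec.n_signal_edges))
        for k in range(spec.n_signal_edges):
            x[:, edge_i[k]] += latent[:, k] * loading[k]
            x[:, edge_j[k]] += latent[:, k] * loading[k]

        tissue = _smooth_noise(rng, t, 3)
        x = x + tissue @ rng.normal(0.0, _TISSUE_MIX_SD, size=(3, r))

        motion = np.cumsum(
            np.column_stack(
                [
                    rng.normal(0.0, 0.02, size=(t, 3)),  # translations, mm
                    rng.normal(0.0, 4e-4, size=(t, 3)),  # rotations, rad
                ]
            ),
            axis=0,
        )
        if spec.motion_spike_rate > 0:
            spike_frames = np.nonzero(
                rng.random(t - 1) < spec.motion_spike_rate
            )[0] + 1
            for frame in spike_frames:
                axis = int(rng.integers(0, 3))
                jump = rng.uniform(0.6, 1.5) * (1 if rng.random() < 0.5 else -1)
                motion[frame:, axis] += jump  # step => FD spike at this frame
                x[frame] += rng.standard_normal(r) * _SPIKE_ARTIFACT_SD

        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{s:04d}",
                timeseries=x,
                motion=motion,
                tissue_signals=tissue,
                tr_seconds=spec.tr_seconds,
                ls_score=float(ls[s]),
            )
        )

    return SyntheticCohort(
        subjects=subjects,
        true_signal_edges=signal_edges,
        true_effects=np.full(spec.n_signal_edges, spec.effect_size),
        ls_scores=ls,
        spec=spec,
    )
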