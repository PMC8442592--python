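"""ROI time-series post-processing and Fisher-z connectome construction.

The preprocessing chain mirrors the standard resting-state fMRI recipe for
connectome-based predictive modeling: drop the initial frames of each run,
regress out nuisance signals (linear trend, six rigid-body motion parameters,
mean white-matter / ventricle / gray-matter signals, and the temporal
derivatives of the nine signal regressors), band-pass filter the residuals,
censor high-motion frames by framewise displacement (FD), correlate every ROI
pair, and Fisher r-to-z transform the correlations.  The strict lower triangle
of each subject's z-matrix is vectorized into a canonical edge ordering and
stacked into an ``n_subjects x E`` feature matrix, ``E = R(R-1)/2``.

The fixed processing order is: drop-initial -> nuisance regression ->
band-pass -> scrub -> correlation.  Scrubbing removes only the flagged frame
(no neighbour augmentation), with strict inequality ``FD > threshold``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .exceptions import (
    DataError,
    DegenerateCorrelationError,
    ParameterError,
    PreconditionError,
)

logger = logging.getLogger(__name__)

#: The nine resting-state network labels: the seven canonical cortical
#: networks plus basal ganglia (BG) and cerebellum (CER).
NETWORK_LABELS: tuple[str, ...] = (
    "Vis", "Somat", "DAN", "VAN", "Limb", "FP", "DMN", "BG", "CER",
)

DEFAULT_N_ROIS = 427  # 400 cortical + 17 subcortical + 10 cerebellar


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One subject's raw inputs to the preprocessing chain.

    ``timeseries`` is T x R (arbitrary signal units), ``motion`` is T x 6
    (three translations in mm followed by three rotations in radians), and
    ``tissue_signals`` is T x 3 (white matter, ventricle, gray matter means).
    """

    subject_id: str
    timeseries: np.ndarray
    motion: np.ndarray
    tissue_signals: np.ndarray
    tr_seconds: float
    ls_score: float = np.nan

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.tissue_signals = np.asarray(self.tissue_signals, dtype=float)
        t = self.timeseries.shape[0]
        if t == 0:
            raise DataError(f"subject {self.subject_id}: empty time series")
        if self.timeseries.ndim != 2 or self.timeseries.shape[1] < 2:
            raise DataError(
                f"subject {self.subject_id}: timeseries must be T x R with R > 1"
            )
        if self.motion.shape != (t, 6):
            raise DataError(
                f"subject {self.subject_id}: motion must be T x 6 "
                f"(got {self.motion.shape}, T={t})"
            )
        if self.tissue_signals.shape != (t, 3):
            raise DataError(
                f"subject {self.subject_id}: tissue_signals must be T x 3 "
                f"(got {self.tissue_signals.shape}, T={t})"
            )
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_rois(self) -> int:
        return self.timeseries.shape[1]


@dataclass
class ConnectivityMatrix:
    """R x R symmetric matrix of Fisher-z connectivity; diagonal unused."""

    values: np.ndarray
    roi_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = self.values.shape[0]
        if self.values.shape != (r, r):
            raise DataError("connectivity matrix must be square")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureMatrix:
    """n_subjects x E matrix of vectorized Fisher-z edges.

    Edge k corresponds to ROI pair ``(i, j)`` with ``i > j`` under the
    canonical strict-lower-triangle row-major ordering (see ``edge_pairs``).
    """

    values: np.ndarray
    n_rois: int
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        e = n_edges(self.n_rois)
        if self.values.ndim != 2 or self.values.shape[1] != e:
            raise DataError(
                f"feature matrix must have E = R(R-1)/2 = {e} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise DataError("subject_ids length must match number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


@dataclass
class NetworkPartition:
    """ROI -> resting-state network assignment over the nine labels."""

    roi_to_network: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = sorted(set(self.roi_to_network) - set(NETWORK_LABELS))
        if bad:
            raise DataError(
                f"unknown network label(s) {bad}; allowed: {list(NETWORK_LABELS)}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_to_network)

    def label_indices(self) -> np.ndarray:
        """Network index (position in NETWORK_LABELS) per ROI."""
        lut = {name: i for i, name in enumerate(NETWORK_LABELS)}
        return np.array([lut[x] for x in self.roi_to_network], dtype=int)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain, defaults per the study recipe."""

    drop_seconds: float = 10.0
    low_hz: float = 0.008
    high_hz: float = 0.1
    fd_threshold_mm: float = 0.5
    head_radius_mm: float = 50.0
    min_frames: int = 50
    filter_order: int = 4


@dataclass
class ExclusionReport:
    """Subjects dropped during feature assembly and why."""

    excluded: list[tuple[str, str]] = field(default_factory=list)

    def add(self, subject_id: str, reason: str) -> None:
        self.excluded.append((subject_id, reason))


# ---------------------------------------------------------------------------
# Edge ordering helpers
# ---------------------------------------------------------------------------

def n_edges(n_rois: int) -> int:
    """Number of unique off-diagonal edges, E = R(R-1)/2."""
    if n_rois < 2:
        raise ParameterError("n_rois must be >= 2")
    return n_rois * (n_rois - 1) // 2


def edge_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: (row, col) index arrays of the strict lower
    triangle in row-major order, i.e. edge k = i(i-1)/2 + j for i > j."""
    return np.tril_indices(n_rois, k=-1)


def edge_position(i: int, j: int) -> int:
    """Edge index of ROI pair (i, j), 0-based, order-insensitive."""
    if i == j:
        raise ParameterError("diagonal entries are not edges")
    i, j = (i, j) if i > j else (j, i)
    return i * (i - 1) // 2 + j


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def drop_initial(record: SubjectRecord, seconds: float = 10.0) -> SubjectRecord:
    """Remove the first ``ceil(seconds / tr)`` frames from every per-frame array."""
    if seconds < 0:
        raise ParameterError("seconds must be non-negative")
    n_drop = math.ceil(seconds / record.tr_seconds - 1e-12)
    if n_drop >= record.n_timepoints:
        raise PreconditionError(
            f"subject {record.subject_id}: dropping {n_drop} frames leaves "
            f"nothing of a {record.n_timepoints}-frame series"
        )
    if n_drop == 0:
        return record
    return replace(
        record,
        timeseries=record.timeseries[n_drop:],
        motion=record.motion[n_drop:],
        tissue_signals=record.tissue_signals[n_drop:],
    )


def build_nuisance(record: SubjectRecord) -> np.ndarray:
    """Assemble the T x 20 nuisance regressor matrix.

    Columns: intercept, centered linear trend, 6 motion parameters, 3 tissue
    signals, then backward-difference temporal derivatives of the 9 signal
    regressors (first row zero).
    """
    t = record.n_timepoints
    trend = np.arange(t, dtype=float)
    trend -= trend.mean()
    signals = np.column_stack([record.motion, record.tissue_signals])  # T x 9
    derivs = np.zeros_like(signals)
    derivs[1:] = np.diff(signals, axis=0)
    return np.column_stack([np.ones(t), trend, signals, derivs])


def regress_nuisance(timeseries: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Per-ROI OLS residuals of the time series against the regressors."""
    timeseries = np.asarray(timeseries, dtype=float)
    regressors = np.asarray(regressors, dtype=float)
    t, p = regressors.shape
    if timeseries.shape[0] != t:
        raise DataError("timeseries and regressors must share T")
    if t <= p:
        raise PreconditionError(f"need T > P regressors (T={t}, P={p})")
    rank = np.linalg.matrix_rank(regressors)
    if rank < p:
        logger.warning(
            "nuisance matrix is rank-deficient (rank %d of %d); "
            "solving via pseudoinverse", rank, p,
        )
    beta, *_ = np.linalg.lstsq(regressors, timeseries, rcond=None)
    return timeseries - regressors @ beta


def bandpass(
    timeseries: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    A 4th-order Butterworth is applied forward-backward (``filtfilt``), so the
    effective magnitude response is the square of the single-pass response and
    the phase is zero.
    """
    nyquist = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist:.4g} Hz)"
        )
    sos = sp_signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds,
        output="sos",
    )
    return sp_signal.sosfiltfilt(sos, np.asarray(timeseries, dtype=float), axis=0)


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement from T x 6 motion parameters.

    ``FD_t = sum |delta translation| + head_radius * sum |delta rotation|``,
    with translations in mm, rotations in radians, and FD at the first frame
    defined as 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError("motion must be T x 6")
    if not np.all(np.isfinite(motion)):
        frame = int(np.argwhere(~np.isfinite(motion).all(axis=1))[0, 0])
        raise DataError(f"non-finite motion parameter at frame {frame}")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def scrub(
    timeseries: np.ndarray,
    fd: np.ndarray,
    threshold_mm: float = 0.5,
    min_frames: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Censor frames with FD strictly above the threshold.

    Returns ``(censored timeseries, retained-frame mask, flagged)`` where
    ``flagged`` is True when fewer than ``min_frames`` frames survive; the
    caller decides whether to exclude the subject.
    """
    timeseries = np.asarray(timeseries, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if timeseries.shape[0] != fd.shape[0]:
        raise DataError("timeseries and FD series must share T")
    mask = fd <= threshold_mm  # strict > removed, boundary frames retained
    flagged = int(mask.sum()) < min_frames
    if flagged:
        logger.warning(
            "scrubbing retained %d < %d frames; subject flagged for exclusion",
            int(mask.sum()), min_frames,
        )
    return timeseries[mask], mask, flagged


def connectivity(
    timeseries: np.ndarray, roi_ids: tuple[str, ...] | None = None
) -> ConnectivityMatrix:
    """Pearson-correlate all ROI pairs and Fisher r-to-z transform.

    Raises ``DegenerateCorrelationError`` if any off-diagonal |r| is
    numerically 1 (the z value would be infinite) and ``DataError`` for
    zero-variance ROIs.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.shape[0] < 3:
        raise PreconditionError("need at least 3 retained frames")
    sd = x.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise DataError(f"zero-variance ROI(s) at index {dead.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    worst = np.abs(r[off]).max()
    if worst >= 1.0 - 1e-12:
        i, j = np.argwhere(off & (np.abs(r) >= 1.0 - 1e-12))[0]
        raise DegenerateCorrelationError(
            f"|r| = {worst:.15f} between ROIs {i} and {j}; "
            "Fisher z would be infinite"
        )
    np.fill_diagonal(r, 0.0)  # diagonal excluded downstream; avoid atanh(1)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # exact symmetry against float asymmetry
    return ConnectivityMatrix(values=z, roi_ids=roi_ids)


def vectorize(matrix: ConnectivityMatrix | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Strict lower triangle in row-major order -> length-E edge vector."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DataError("expected a square matrix")
    if not np.allclose(values, values.T, atol=atol, rtol=0):
        raise DataError("matrix is asymmetric beyond tolerance")
    rows, cols = edge_pairs(values.shape[0])
    return values[rows, cols]


def inverse_vectorize(edge_vector: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric R x R matrix (zero diagonal) from an edge vector."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    if edge_vector.shape != (n_edges(n_rois),):
        raise DataError(
            f"edge vector length {edge_vector.shape} does not match R={n_rois}"
        )
    out = np.zeros((n_rois, n_rois))
    rows, cols = edge_pairs(n_rois)
    out[rows, cols] = edge_vector
    out[cols, rows] = edge_vector
    return out


def preprocess_subject(
    record: SubjectRecord, config: PreprocessConfig | None = None
) -> tuple[np.ndarray | None, str | None]:
    """Run the full chain on one subject.

    Returns ``(edge_vector, None)`` on success or ``(None, reason)`` when the
    subject is flagged for exclusion by the scrubbing minimum.
    """
    cfg = config or PreprocessConfig()
    rec = drop_initial(record, cfg.drop_seconds)
    nuisance = build_nuisance(rec)
    resid = regress_nuisance(rec.timeseries, nuisance)
    filtered = bandpass(
        resid, rec.tr_seconds, cfg.low_hz, cfg.high_hz, cfg.filter_order
    )
    fd = framewise_displacement(rec.motion, cfg.head_radius_mm)
    censored, _, flagged = scrub(
        filtered, fd, cfg.fd_threshold_mm, cfg.min_frames
    )
    if flagged:
        return None, (
            f"only {censored.shape[0]} frames retained after FD scrubbing "
            f"(minimum {cfg.min_frames})"
        )
    conn = connectivity(censored)
    return vectorize(conn), None


def assemble_features(
    records: list[SubjectRecord], config: PreprocessConfig | None = None
) -> tuple[FeatureMatrix, ExclusionReport]:
    """Preprocess every subject and stack edge vectors into a FeatureMatrix.

    Rows follow input subject order; flagged subjects are excluded and listed
    in the exclusion report.
    """
    if not records:
        raise PreconditionError("no subjects supplied")
    n_rois = records[0].n_rois
    for rec in records:
        if rec.n_rois != n_rois:
            raise DataError(
                f"subject {rec.subject_id} has R={rec.n_rois}, expected {n_rois}"
            )
    report = ExclusionReport()
    rows, kept_ids = [], []
    for rec in records:
        vec, reason = preprocess_subject(rec, config)
        if vec is None:
            report.add(rec.subject_id, reason)
            logger.info("excluding subject %s: %s", rec.subject_id, reason)
        else:
            rows.append(vec)
            kept_ids.append(rec.subject_id)
    if not rows:
        raise DataError("every subject was excluded by scrubbing")
    fm = FeatureMatrix(
        values=np.vstack(rows), n_rois=n_rois, subject_ids=tuple(kept_ids)
    )
    return fm, report


def default_atlas(n_rois: int = DEFAULT_N_ROIS) -> NetworkPartition:
    """Default 427-ROI partition: 400 cortical parcels cycled over the seven
    canonical networks, 17 subcortical ROIs labeled BG, 10 cerebellar labeled
    CER.  For other R the same 400/17/10 proportions are used."""
    if n_rois < 9:
        raise ParameterError("n_rois must be >= 9 to cover nine networks")
    n_cer = max(1, round(n_rois * 10 / 427))
    n_bg = max(1, round(n_rois * 17 / 427))
    n_cortical = n_rois - n_bg - n_cer
    cortical = [NETWORK_LABELS[i % 7] for i in range(n_cortical)]
    return NetworkPartition(
        roi_to_network=tuple(cortical + ["BG"] * n_bg + ["CER"] * n_cer)
    )
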