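"""Readers and writers for the pipeline's file formats.

All tabular formats are TSV with explicit headers; floats are written with a
fixed ``%.10g`` format so that repeated runs with equal seeds are
byte-identical.  Motion files carry a units comment line (translations in mm,
rotations in radians) that readers require.  Atlas label files are 1-based on
disk (``roi_index`` starting at 1) and converted to 0-based indices at this
boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    NETWORK_LABELS,
    NetworkPartition,
    FeatureMatrix,
    SubjectRecord,
)
from .exceptions import DataError
from .predict import CVConfig, FittedPipeline, PCAModel, RidgeFold

FLOAT_FMT = "%.10g"
MOTION_UNITS_LINE = "# units: translations mm, rotations radians"
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("white_matter", "ventricle", "gray_matter")


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: FLOAT_FMT % v)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    _fmt_frame(df).to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Per-subject files
# ---------------------------------------------------------------------------

def write_timeseries(path: str | Path, timeseries: np.ndarray,
                     roi_names: list[str] | None = None) -> None:
    t, r = timeseries.shape
    names = roi_names or [f"roi_{i + 1:03d}" for i in range(r)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        np.savetxt(fh, timeseries, fmt=FLOAT_FMT, delimiter="\t")


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise DataError(f"{path}: malformed numeric row ({exc})") from exc
    if data.shape[1] != len(header):
        raise DataError(
            f"{path}: header lists {len(header)} ROIs but rows have "
            f"{data.shape[1]} columns"
        )
    return data, header


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(MOTION_UNITS_LINE + "\n")
        fh.write("\t".join(MOTION_COLUMNS) + "\n")
        np.savetxt(fh, motion, fmt=FLOAT_FMT, delimiter="\t")


def read_motion(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        units = fh.readline().strip()
        if not units.startswith("#") or "mm" not in units or "radians" not in units:
            raise DataError(
                f"{path}, line 1: expected a units comment declaring mm "
                f"translations and radian rotations, got {units!r}"
            )
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MOTION_COLUMNS:
            raise DataError(
                f"{path}, line 2: expected columns {list(MOTION_COLUMNS)}, "
                f"got {header}"
            )
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != 6:
        raise DataError(f"{path}: motion must have 6 columns")
    return data


def write_tissue(path: str | Path, tissue: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TISSUE_COLUMNS) + "\n")
        np.savetxt(fh, tissue, fmt=FLOAT_FMT, delimiter="\t")


def read_tissue(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TISSUE_COLUMNS:
            raise DataError(
                f"{path}, line 1: expected columns {list(TISSUE_COLUMNS)}, "
                f"got {header}"
            )
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[1] != 3:
        raise DataError(f"{path}: tissue signals must have 3 columns")
    return data


# ---------------------------------------------------------------------------
# Cohort-level files
# ---------------------------------------------------------------------------

def read_subject_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "ls"):
        if col not in df.columns:
            raise DataError(
                f"{path}, line 1: required column {col!r} missing from header "
                f"{list(df.columns)}"
            )
    if df["ls"].isna().any():
        row = int(df.index[df["ls"].isna()][0]) + 2  # header is line 1
        raise DataError(f"{path}, line {row}: missing LS score")
    return df


def write_subject_table(path: str | Path, subject_ids, ls_scores) -> None:
    write_tsv(
        pd.DataFrame({"subject_id": list(subject_ids), "ls": np.asarray(ls_scores)}),
        path,
    )


def read_atlas_labels(path: str | Path) -> NetworkPartition:
    """Atlas table: roi_index (1-based), roi_name, network (nine labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_index", "roi_name", "network"):
        if col not in df.columns:
            raise DataError(f"{path}, line 1: required column {col!r} missing")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["roi_index"].to_numpy(), expected):
        raise DataError(
            f"{path}: roi_index must run 1..{len(df)} in order (1-based)"
        )
    bad = df.loc[~df["network"].isin(NETWORK_LABELS)]
    if len(bad):
        line = int(bad.index[0]) + 2
        raise DataError(
            f"{path}, line {line}: unknown network label "
            f"{bad['network'].iloc[0]!r}; allowed: {list(NETWORK_LABELS)}"
        )
    return NetworkPartition(roi_to_network=tuple(df["network"]))


def write_atlas_labels(path: str | Path, partition: NetworkPartition) -> None:
    df = pd.DataFrame(
        {
            "roi_index": np.arange(1, partition.n_rois + 1),
            "roi_name": [f"roi_{i + 1:03d}" for i in range(partition.n_rois)],
            "network": list(partition.roi_to_network),
        }
    )
    write_tsv(df, path)


def write_feature_matrix(path: str | Path, fm: FeatureMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_rois: {fm.n_rois}\n")
        fh.write(
            "subject_id\t"
            + "\t".join(f"e{k}" for k in range(fm.n_edges))
            + "\n"
        )
        for sid, row in zip(fm.subject_ids, fm.values):
            fh.write(sid + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# n_rois:"):
            raise DataError(f"{path}, line 1: expected '# n_rois: <R>' header")
        n_rois = int(meta.split(":")[1])
        df = pd.read_csv(fh, sep="\t")
    return FeatureMatrix(
        values=df.drop(columns="subject_id").to_numpy(dtype=float),
        n_rois=n_rois,
        subject_ids=tuple(df["subject_id"]),
    )


def write_truth(path: str | Path, signal_edges: np.ndarray, effect_size: float) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "signal_edges": [int(k) for k in signal_edges],
                "effect_size": float(effect_size),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_truth(path: str | Path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        obj = json.load(fh)
    return np.asarray(obj["signal_edges"], dtype=int), float(obj["effect_size"])


# ---------------------------------------------------------------------------
# Cohort directory layout
# ---------------------------------------------------------------------------

def write_cohort_dir(directory: str | Path, subjects: list[SubjectRecord]) -> None:
    """One timeseries/motion/tissue TSV trio per subject plus a subject table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in subjects:
        write_timeseries(directory / f"{rec.subject_id}_timeseries.tsv", rec.timeseries)
        write_motion(directory / f"{rec.subject_id}_motion.tsv", rec.motion)
        write_tissue(directory / f"{rec.subject_id}_tissue.tsv", rec.tissue_signals)
    write_subject_table(
        directory / "subjects.tsv",
        [r.subject_id for r in subjects],
        [r.ls_score for r in subjects],
    )


def read_cohort_dir(directory: str | Path, tr_seconds: float) -> list[SubjectRecord]:
    """Read every subject listed in ``subjects.tsv``, cross-validating the
    per-file frame counts."""
    directory = Path(directory)
    table = read_subject_table(directory / "subjects.tsv")
    records = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        ts, _ = read_timeseries(directory / f"{sid}_timeseries.tsv")
        motion = read_motion(directory / f"{sid}_motion.tsv")
        tissue = read_tissue(directory / f"{sid}_tissue.tsv")
        if motion.shape[0] != ts.shape[0] or tissue.shape[0] != ts.shape[0]:
            raise DataError(
                f"subject {sid}: frame counts disagree across files "
                f"(timeseries {ts.shape[0]}, motion {motion.shape[0]}, "
                f"tissue {tissue.shape[0]})"
            )
        records.append(
            SubjectRecord(
                subject_id=sid,
                timeseries=ts,
                motion=motion,
                tissue_signals=tissue,
                tr_seconds=tr_seconds,
                ls_score=float(row["ls"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Model serialization: JSON metadata + npz arrays
# ---------------------------------------------------------------------------

def save_pipeline(pipeline: FittedPipeline, stem: str | Path) -> None:
    stem = Path(stem)
    arrays = {
        "pca_center": pipeline.pca.center,
        "pca_transform": pipeline.pca.transform,
        "pca_explained_variance": pipeline.pca.explained_variance,
    }
    meta = {
        "n_subjects": pipeline.n_subjects,
        "n_repeats": len(pipeline.repeats),
        "n_folds": pipeline.config.n_folds,
        "inner_folds": pipeline.config.inner_folds,
        "seed": pipeline.config.seed,
        "lambda_grid": [float(v) for v in pipeline.config.lambda_grid],
        "folds": [],
    }
    for rep_i, folds in enumerate(pipeline.repeats):
        for fold_i, f in enumerate(folds):
            key = f"rep{rep_i}_fold{fold_i}"
            arrays[f"{key}_coef"] = f.coefficients
            arrays[f"{key}_train"] = f.train_idx
            arrays[f"{key}_test"] = f.test_idx
            meta["folds"].append(
                {
                    "repeat": rep_i,
                    "fold": fold_i,
                    "intercept": f.intercept,
                    "lambda": f.lam,
                }
            )
    np.savez(str(stem) + ".npz", **arrays)
    with open(str(stem) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_pipeline(stem: str | Path) -> FittedPipeline:
    stem = Path(stem)
    with open(str(stem) + ".json") as fh:
        meta = json.load(fh)
    arrays = np.load(str(stem) + ".npz")
    pca = PCAModel(
        center=arrays["pca_center"],
        transform=arrays["pca_transform"],
        explained_variance=arrays["pca_explained_variance"],
    )
    config = CVConfig(
        n_folds=meta["n_folds"],
        inner_folds=meta["inner_folds"],
        lambda_grid=np.asarray(meta["lambda_grid"]),
        seed=meta["seed"],
        n_repeats=meta["n_repeats"],
    )
    repeats: list[list[RidgeFold]] = [[] for _ in range(meta["n_repeats"])]
    for entry in meta["folds"]:
        key = f"rep{entry['repeat']}_fold{entry['fold']}"
        repeats[entry["repeat"]].append(
            RidgeFold(
                coefficients=arrays[f"{key}_coef"],
                intercept=entry["intercept"],
                lam=entry["lambda"],
                train_idx=arrays[f"{key}_train"],
                test_idx=arrays[f"{key}_test"],
            )
        )
    return FittedPipeline(
        pca=pca, repeats=repeats, config=config, n_subjects=meta["n_subjects"]
    )
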