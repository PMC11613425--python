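"""Tab-delimited file formats and model serialization.

Views and metadata travel as UTF-8 TSV with a ``subject_id`` first
column; fitted models are stored as a single JSON container holding
weights, regularization, standardization parameters, dropped features
and provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .mcca import MultisetCCA
from .simulate import MultiViewDataset

__all__ = ["read_view_tsv", "write_view_tsv", "read_metadata_tsv",
           "write_metadata_tsv", "write_dataset", "read_dataset",
           "save_model", "load_model", "align_views"]

logger = logging.getLogger(__name__)


def _read_table(path, numeric: bool) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id', "
                         f"got {df.columns[0]!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_id(s): {dupes[:5]}")
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based + header
        raise ValueError(f"{path}: missing value at line {line}")
    df = df.set_index("subject_id")
    if numeric:
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce").isna()
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise ValueError(
                    f"{path}: non-numeric cell in column {col!r} "
                    f"at line {line}") from exc
    return df


def read_view_tsv(path) -> pd.DataFrame:
    """Read one view (all-numeric features, subject_id index)."""
    return _read_table(path, numeric=True)


def write_view_tsv(view: pd.DataFrame, path) -> None:
    view.to_csv(path, sep="\t", index_label="subject_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read subject metadata; numeric columns are converted, categorical
    ones (site, family, group) kept as strings."""
    df = _read_table(path, numeric=False)
    for col in df.columns:
        if col not in ("site", "family", "group"):
            converted = pd.to_numeric(df[col], errors="coerce")
            if not converted.isna().any():
                df[col] = converted
    return df


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="subject_id")


def align_views(views: list[pd.DataFrame],
                metadata: pd.DataFrame | None = None) -> list[pd.DataFrame]:
    """Align views (and optionally metadata) on the intersection of
    subject IDs, re-ordering rows to match the first view.

    Views already aligned pass through unchanged; re-orderings are
    logged.  Subjects missing from any view are dropped.
    """
    common = views[0].index
    for v in views[1:]:
        common = common.intersection(v.index)
    if metadata is not None:
        common = common.intersection(metadata.index)
    common = views[0].index[views[0].index.isin(common)]  # first view's order
    out = []
    for i, v in enumerate(views):
        if not v.index.equals(common):
            logger.info("view %d re-aligned to the shared subject order", i)
        out.append(v.loc[common])
    if metadata is not None:
        out.append(metadata.loc[common])
    return out


def write_dataset(dataset: MultiViewDataset, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, view in zip(dataset.view_names, dataset.views):
        p = outdir / f"{name}.tsv"
        write_view_tsv(view, p)
        paths.append(p)
    p = outdir / "metadata.tsv"
    write_metadata_tsv(dataset.metadata, p)
    paths.append(p)
    return paths


def read_dataset(view_paths, metadata_path) -> MultiViewDataset:
    views = [read_view_tsv(p) for p in view_paths]
    metadata = read_metadata_tsv(metadata_path)
    *views, metadata = align_views(views, metadata)
    names = [Path(p).stem for p in view_paths]
    return MultiViewDataset(views=views, metadata=metadata, view_names=names)


def save_model(model: MultisetCCA, path, provenance: dict | None = None
               ) -> None:
    """Serialize a fitted model (weights, c, standardization, dropped
    features, provenance) to a JSON container."""
    payload = {
        "n_components": int(model.n_components),
        "c": [float(x) for x in model.c_],
        "n_views": int(model.n_views_),
        "feature_names": model.feature_names_in_,
        "kept_idx": [idx.tolist() for idx in model.kept_idx_],
        "dropped_features": model.dropped_features_,
        "means": [m.tolist() for m in model.means_],
        "scales": [s.tolist() for s in model.scales_],
        "weights": [w.tolist() for w in model.weights_],
        "objective_values": model.objective_values_.tolist(),
        "scale": bool(model.scale),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> MultisetCCA:
    payload = json.loads(Path(path).read_text())
    model = MultisetCCA(n_components=payload["n_components"],
                        c=payload["c"], scale=payload["scale"])
    model.n_views_ = payload["n_views"]
    model.c_ = np.asarray(payload["c"], dtype=float)
    model.feature_names_in_ = payload["feature_names"]
    model.kept_idx_ = [np.asarray(i, dtype=int) for i in payload["kept_idx"]]
    model.dropped_features_ = payload["dropped_features"]
    model.means_ = [np.asarray(m, dtype=float) for m in payload["means"]]
    model.scales_ = [np.asarray(s, dtype=float) for s in payload["scales"]]
    model.weights_ = [np.asarray(w, dtype=float) for w in payload["weights"]]
    model.objective_values_ = np.asarray(payload["objective_values"])
    return model
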