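"""Matrix I/O and model serialization.

Cohorts are read from CSV/TSV (first row = feature names, one sample per
row; the outcome in a sibling single-column file).  Models serialize to
JSON — human-auditable, and consistent with the privacy stance that only
parameters leave the servers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CoefficientModel, TaskDataset
from .inmf import INMFModel

_MODEL_VERSION = 1


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(matrix_path, outcome_path, task_id: str | None = None) -> TaskDataset:
    """Read one cohort: a samples-by-features matrix plus its outcome file.

    Missing values and non-numeric cells are rejected with row/column
    diagnostics; the outcome file must hold exactly one value per sample.
    """
    matrix_path = Path(matrix_path)
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path))
    bad = df.columns[df.dtypes == object]
    if len(bad):
        raise ValueError(f"non-numeric cells in columns: {list(bad)}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        cols = df.columns[df.isna().any(axis=0)].tolist()
        raise ValueError(f"missing values at rows {rows}, columns {cols}")
    outcome_path = Path(outcome_path)
    y = pd.read_csv(outcome_path, sep=_sep_for(outcome_path), header=None).to_numpy().ravel()
    if y.shape[0] == df.shape[0] + 1 and isinstance(y[0], str):
        y = y[1:].astype(float)  # tolerate a header line
    if y.shape[0] != df.shape[0]:
        raise ValueError(
            f"outcome length {y.shape[0]} != sample count {df.shape[0]}"
        )
    return TaskDataset(
        X=df.to_numpy(dtype=float),
        y=np.asarray(y, dtype=float),
        feature_names=list(df.columns),
        task_id=task_id or matrix_path.stem,
    )


def write_cohort(dataset: TaskDataset, matrix_path, outcome_path) -> None:
    """Write a cohort back to CSV/TSV (inverse of :func:`read_cohort`)."""
    matrix_path = Path(matrix_path)
    pd.DataFrame(dataset.X, columns=dataset.feature_names).to_csv(
        matrix_path, sep=_sep_for(matrix_path), index=False
    )
    pd.Series(dataset.y).to_csv(outcome_path, index=False, header=False)


def write_model(model, path, extra: dict | None = None) -> None:
    """Serialize a coefficient or iNMF model to JSON.

    An iNMF model contains the shared factor H and the scalar objective
    only — the cohort-specific factors are server-local and are not part of
    any client-side serialization under the shared-only policy.
    """
    if isinstance(model, CoefficientModel):
        doc = {
            "version": _MODEL_VERSION,
            "kind": "coefficients",
            "loss": model.loss,
            "W": model.W.tolist(),
            "c": model.c.tolist(),
            "feature_names": model.feature_names,
            "task_ids": model.task_ids,
        }
        if model.standardize is not None:
            doc["standardize"] = {
                key: {t: np.asarray(v).tolist() for t, v in d.items()}
                for key, d in model.standardize.items()
            }
    elif isinstance(model, INMFModel):
        doc = {
            "version": _MODEL_VERSION,
            "kind": "inmf",
            "H": model.H.tolist(),
            "rank": model.rank,
            "lam_het": model.lam_het,
            "objective": model.objective,
            "objective_history": list(model.objective_history),
            "n_iter": model.n_iter,
            "start": model.start,
            "seed": model.seed,
            "feature_names": model.feature_names,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    if extra:
        doc["extra"] = extra
    Path(path).write_text(json.dumps(doc))


def read_model(path):
    """Inverse of :func:`write_model`; rejects unknown format versions."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("version")
    if version != _MODEL_VERSION:
        raise ValueError(f"unknown model format version {version!r}")
    if doc["kind"] == "coefficients":
        std = doc.get("standardize")
        if std is not None:
            std = {
                key: {t: np.asarray(v, dtype=float) for t, v in d.items()}
                for key, d in std.items()
            }
        return CoefficientModel(
            W=np.asarray(doc["W"], dtype=float),
            c=np.asarray(doc["c"], dtype=float),
            feature_names=doc["feature_names"],
            task_ids=doc["task_ids"],
            loss=doc.get("loss", "ls"),
            standardize=std,
        )
    if doc["kind"] == "inmf":
        return INMFModel(
            H=np.asarray(doc["H"], dtype=float),
            rank=int(doc["rank"]),
            lam_het=float(doc["lam_het"]),
            objective=float(doc["objective"]),
            objective_history=[float(v) for v in doc["objective_history"]],
            n_iter=int(doc["n_iter"]),
            start=int(doc["start"]),
            seed=int(doc["seed"]),
            feature_names=doc["feature_names"],
        )
    raise ValueError(f"unknown model kind {doc['kind']!r}")
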