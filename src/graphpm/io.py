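"""Delimited-text and YAML I/O for every pipeline artefact.

All tables are plain delimited text (TSV for matrices, CSV for subject
tables) with missing values encoded as empty fields; configuration (ROI
maps, model specs, run configs) is YAML.  Writers and readers round-trip
to full precision; the connectome reader validates symmetry within 1e-10.

ROI maps use **0-based node indices**.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, ModelSpec
from .connectome import Connectome, TimeSeries
from .metrics import MetricVector, RoiMap

__all__ = [
    "read_time_series",
    "write_matrix",
    "read_matrix",
    "write_connectome",
    "read_connectome",
    "write_cohort_table",
    "read_cohort_table",
    "write_metric_vectors",
    "read_metric_vectors",
    "read_roi_map",
    "write_roi_map",
    "read_model_spec",
    "write_predictions",
    "write_json",
]

_FLOAT_FMT = "%.17g"


def write_matrix(path: str | Path, m: np.ndarray, labels: Sequence[str] | None = None) -> None:
    """Square or rectangular numeric matrix as TSV, optionally labelled."""
    df = pd.DataFrame(np.asarray(m))
    if labels is not None:
        df.index = list(labels)[: df.shape[0]]
        if df.shape[1] == len(labels):
            df.columns = list(labels)
    df.to_csv(path, sep="\t", float_format="%.17g", header=labels is not None,
              index=labels is not None)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited matrix; returns (values, labels-or-None)."""
    with open(path) as fh:
        first = fh.readline()
    has_header = any(_non_numeric(tok) for tok in first.strip().split("\t") if tok)
    if has_header:
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df.to_numpy(dtype=float), [str(c) for c in df.columns]
    return np.loadtxt(path, delimiter="\t", ndmin=2), None


def _non_numeric(tok: str) -> bool:
    try:
        float(tok)
        return False
    except ValueError:
        return True


def read_time_series(
    paths: Sequence[str | Path],
    subject_id: str,
    state: str,
) -> TimeSeries:
    """One delimited file per run: nodes as rows, time as columns."""
    runs = []
    labels: list[str] | None = None
    for p in paths:
        m, lab = read_matrix(p)
        runs.append(m)
        if lab is not None and len(lab) == m.shape[1]:
            # header row labelled columns (time); node labels come from index
            lab = None
        labels = labels or lab
    if labels is None:
        labels = [f"node{i:03d}" for i in range(runs[0].shape[0])]
    return TimeSeries(subject_id, state, runs, labels)


def write_connectome(path: str | Path, c: Connectome) -> None:
    write_matrix(path, c.z, list(c.node_labels))


def read_connectome(path: str | Path, subject_id: str, state: str) -> Connectome:
    z, labels = read_matrix(path)
    if labels is None:
        labels = [f"node{i:03d}" for i in range(z.shape[0])]
    if not np.allclose(z, z.T, atol=1e-10):
        raise ValueError(f"{path}: connectome asymmetric beyond 1e-10")
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, 0.0)
    return Connectome(subject_id, state, z, labels)


def write_cohort_table(path: str | Path, cohort: CohortTable) -> None:
    cohort.data.to_csv(path, index_label="subject_id", float_format="%.17g")


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, index_col="subject_id")
    return CohortTable(df)


def write_metric_vectors(path: str | Path, mvs: Iterable[MetricVector]) -> None:
    """Long-format table: subject, state, metric_name, value."""
    rows = [
        {"subject_id": mv.subject_id, "state": mv.state,
         "metric_name": name, "value": value}
        for mv in mvs
        for name, value in mv.values.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_metric_vectors(path: str | Path) -> list[MetricVector]:
    df = pd.read_csv(path)
    out = []
    for (sid, state), grp in df.groupby(["subject_id", "state"], sort=True):
        values = dict(zip(grp["metric_name"], grp["value"].astype(float)))
        out.append(MetricVector(str(sid), str(state), values))
    return out


def read_roi_map(path: str | Path) -> RoiMap:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw.get("roi_map", raw)
    return RoiMap({str(k): [int(i) for i in v] for k, v in entries.items()})


def write_roi_map(path: str | Path, roi: RoiMap) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"roi_map": {k: list(map(int, v)) for k, v in roi.entries.items()}}, fh)


def read_model_spec(raw: Mapping | str | Path) -> ModelSpec:
    """ModelSpec from a YAML file or an already-parsed mapping."""
    if not isinstance(raw, Mapping):
        with open(raw) as fh:
            raw = yaml.safe_load(fh)
    kw = dict(raw)
    for key in ("candidate_states", "candidate_metrics"):
        if key in kw and kw[key] is not None:
            kw[key] = tuple(kw[key])
    kw.pop("cv", None)
    kw.pop("compare", None)
    kw.pop("permutation", None)
    kw.pop("cpm", None)
    kw.pop("elastic_net", None)
    return ModelSpec(**kw)


def write_predictions(path: str | Path, result) -> None:
    """Per-subject prediction table plus a JSON summary sidecar."""
    path = Path(path)
    result.to_frame().to_csv(path, index=False, float_format="%.17g")
    summary = {
        "model": result.model,
        "scheme": result.scheme,
        "n_used": result.n_used,
        "mse": result.mse,
        "pearson_r": result.pearson_r,
    }
    if result.permutation is not None:
        summary["permutation_p"] = result.permutation.p
        summary["n_perm"] = result.permutation.n_perm
    write_json(path.with_suffix(".summary.json"), summary)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
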