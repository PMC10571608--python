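"""Cohort tables, model specifications, and feature assembly.

A cohort table holds, per subject, the three reward-related symptom scales
(anhedonia, impulsivity, mania) at baseline and at the 3- and 6-month
follow-ups, a psychotropic medication-load covariate, and a diagnostic
group label (e.g. unipolar / bipolar).  Symptom columns are named
``"<symptom>_<timepoint>"``.

A :class:`ModelSpec` fixes one prediction problem: the target (symptom,
time point), its transform, the covariate set implied by the design
(cross-sectional targets covary the two other baseline scales; follow-up
targets covary all three baseline scales; medication load is always
included), and the candidate feature pool (states and metric names).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .metrics import MetricVector

__all__ = [
    "SYMPTOMS",
    "TIMEPOINTS",
    "CohortTable",
    "ModelSpec",
    "assemble_features",
]

SYMPTOMS = ("anhedonia", "impulsivity", "mania")
TIMEPOINTS = ("baseline", "3m", "6m")


def symptom_column(symptom: str, timepoint: str) -> str:
    return f"{symptom}_{timepoint}"


@dataclass
class CohortTable:
    """Subjects x clinical variables, indexed by subject id.

    ``data`` must contain the nine symptom columns (missing values allowed),
    ``medication_load``, and ``group``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = [symptom_column(s, t) for s in SYMPTOMS for t in TIMEPOINTS]
        required += ["medication_load", "group"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        med = self.data["medication_load"]
        if not np.all(np.isfinite(med.dropna().to_numpy(dtype=float))):
            raise ValueError("medication_load contains non-finite values")

    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    def target(self, symptom: str, timepoint: str) -> pd.Series:
        return self.data[symptom_column(symptom, timepoint)].astype(float)

    def groups(self) -> pd.Series:
        return self.data["group"]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one symptom-prediction model.

    Parameters
    ----------
    target_symptom, target_timepoint :
        What to predict.  ``transform="log1p"`` is the default for the
        mania scale (skewed scores); otherwise no transform.
    candidate_states :
        Cognitive states whose graph metrics form the candidate pool
        (selection spans all states in one pool).
    candidate_metrics :
        Restrict the metric names entering the pool; ``None`` keeps every
        metric available.
    selection :
        ``"abs"`` ranks candidates by \\|Pearson r\\| (default), ``"signed"``
        by r.
    """

    target_symptom: str
    target_timepoint: str = "baseline"
    transform: str | None = None
    candidate_states: tuple[str, ...] = ("task", "rest")
    candidate_metrics: tuple[str, ...] | None = None
    selection: str = "abs"
    medication_covariate: str = "medication_load"

    def __post_init__(self) -> None:
        if self.target_symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {self.target_symptom!r}")
        if self.target_timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown time point {self.target_timepoint!r}")
        if self.transform is None:
            object.__setattr__(
                self, "transform",
                "log1p" if self.target_symptom == "mania" else "none",
            )
        if self.transform not in ("none", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.selection not in ("abs", "signed"):
            raise ValueError("selection must be 'abs' or 'signed'")

    @property
    def target_column(self) -> str:
        return symptom_column(self.target_symptom, self.target_timepoint)

    @property
    def covariate_columns(self) -> list[str]:
        """Baseline-symptom and medication covariates implied by the target.

        Follow-up targets covary all three baseline scales; a baseline
        target covaries the two *other* baseline scales.  The target is
        never its own covariate.
        """
        if self.target_timepoint == "baseline":
            cols = [
                symptom_column(s, "baseline")
                for s in SYMPTOMS
                if s != self.target_symptom
            ]
        else:
            cols = [symptom_column(s, "baseline") for s in SYMPTOMS]
        cols.append(self.medication_covariate)
        assert self.target_column not in cols
        return cols

    def apply_transform(self, y: np.ndarray) -> np.ndarray:
        if self.transform == "log1p":
            return np.log1p(y)
        return np.asarray(y, dtype=float)


def assemble_features(
    metric_vectors: Iterable[MetricVector],
    spec: ModelSpec,
) -> pd.DataFrame:
    """Build the subjects x features table for a model's candidate pool.

    Columns are named ``"<state>:<metric>"`` and ordered canonically:
    states alphabetically, then metric names alphabetically within state.
    Subjects lacking a state's scan get NaN in that state's columns
    (excluded later by per-model pairwise deletion).
    """
    rows: dict[str, dict[str, float]] = {}
    for mv in metric_vectors:
        if mv.state not in spec.candidate_states:
            continue
        for name, value in mv.values.items():
            metric = name
            if spec.candidate_metrics is not None and metric not in spec.candidate_metrics:
                continue
            rows.setdefault(mv.subject_id, {})[f"{mv.state}:{metric}"] = value
    if not rows:
        raise ValueError("no candidate features: check states/metrics in the spec")
    table = pd.DataFrame.from_dict(rows, orient="index")
    ordered = sorted(table.columns, key=lambda c: (c.split(":", 1)[0], c.split(":", 1)[1]))
    table = table[ordered]
    table.index.name = "subject_id"
    return table.sort_index()
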