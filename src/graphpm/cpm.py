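"""Connectome-based predictive modeling (CPM), the head-to-head comparator.

Where the GPM summarises the connectome through one graph metric, the CPM
selects, inside each training fold, the individual edges whose Fisher-z
values correlate with the target at p below a threshold (0.01 by default),
sums them into a per-subject "network strength" (separately for positively
and negatively associated edges), and feeds that strength into the same
covariate-adjusted regression and CV machinery as the GPM.  It can run on
the signed connectome (as originally published) or on the positive-only
connectome used by the GPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, ModelSpec
from .connectome import Connectome
from .model import (
    MIN_TRAIN,
    LOOCV,
    PredictionResult,
    _CVPipeline,
    _ols_predict,
    compare_cv,
)
from .validation import ComparisonResult

__all__ = [
    "EdgeMask",
    "edge_matrix",
    "select_edges",
    "network_strength",
    "ConnectomePredictiveModel",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeMask:
    """A set of selected edges of one polarity.

    ``edges`` holds unordered node pairs (i < j); masks of opposite
    polarity from the same selection are disjoint by construction.
    """

    polarity: str  # "positive" | "negative"
    edges: frozenset[tuple[int, int]]
    p_threshold: float

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if any(i == j for i, j in self.edges):
            raise ValueError("edge mask contains a self-pair")

    def __len__(self) -> int:
        return len(self.edges)


def _edge_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def edge_matrix(connectomes: Mapping[str, Connectome]) -> pd.DataFrame:
    """Vectorise connectomes into a subjects x edges table.

    Columns are the upper-triangle node pairs ``(i, j)`` with i < j, in
    row-major order; the index is the subject id.
    """
    subjects = sorted(connectomes)
    first = connectomes[subjects[0]]
    n = first.n_nodes
    iu, ju = _edge_index(n)
    data = np.empty((len(subjects), iu.size))
    for s, sid in enumerate(subjects):
        c = connectomes[sid]
        if c.n_nodes != n:
            raise ValueError(f"subject {sid}: node count {c.n_nodes} != {n}")
        data[s] = c.z[iu, ju]
    cols = pd.MultiIndex.from_arrays([iu, ju], names=["i", "j"])
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"), columns=cols)


def select_edges(
    edges: pd.DataFrame | np.ndarray,
    target: Sequence[float],
    training_index: Sequence[int],
    p_threshold: float = 0.01,
) -> tuple[EdgeMask, EdgeMask]:
    """Correlate every edge with the target over training subjects.

    Edges with two-sided p below the threshold enter the mask matching the
    sign of the correlation; zero-variance edges are skipped (logged).
    """
    train = np.asarray(training_index)
    if train.size < 3:
        raise ValueError("need at least 3 training subjects for edge selection")
    E = edges.to_numpy(dtype=float) if isinstance(edges, pd.DataFrame) else np.asarray(edges)
    y = np.asarray(target, dtype=float)
    r, p = _edge_correlations(E, y, train)
    skipped = int(np.isnan(r).sum())
    if skipped:
        logger.info("edge selection skipped %d zero-variance edges", skipped)
    hit = (p < p_threshold) & ~np.isnan(r)
    if isinstance(edges, pd.DataFrame):
        pairs = [tuple(int(v) for v in c) for c in edges.columns]
    else:
        # anonymous edge columns: label edge k by the synthetic pair (k, k+1)
        pairs = [(k, k + 1) for k in range(E.shape[1])]
    pos = frozenset(pairs[k] for k in np.flatnonzero(hit & (r > 0)))
    neg = frozenset(pairs[k] for k in np.flatnonzero(hit & (r < 0)))
    return (
        EdgeMask("positive", pos, p_threshold),
        EdgeMask("negative", neg, p_threshold),
    )


def _edge_correlations(E: np.ndarray, y: np.ndarray, train: np.ndarray):
    m = train.size
    Et = E[train]
    yt = y[train]
    Ec = Et - Et.mean(axis=0)
    yc = yt - yt.mean()
    en = np.sqrt((Ec**2).sum(axis=0))
    yn = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec.T @ yc) / (en * yn)
    r[en == 0] = np.nan
    if yn == 0:
        r[:] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((m - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), m - 2)
    p[np.isnan(r)] = np.nan
    return r, p


def network_strength(connectome: Connectome, mask: EdgeMask) -> float:
    """Sum of Fisher-z values over mask edges (each pair counted once)."""
    if len(mask) == 0:
        logger.warning("empty edge mask: network strength is 0")
        return 0.0
    i, j = zip(*mask.edges)
    return float(connectome.z[list(i), list(j)].sum())


class ConnectomePredictiveModel:
    """CPM for one prediction problem on one state's connectomes.

    Parameters
    ----------
    connectomes :
        Mapping subject id -> :class:`Connectome` (one cognitive state).
    cohort, spec :
        Same clinical table and model specification as the GPM (shared
        covariate structure, transform and CV machinery).
    polarity :
        ``"positive"`` or ``"negative"`` feature set (evaluated as separate
        models by default); ``"combined"`` enters both network strengths as
        two predictors in one regression.
    weight_mode :
        ``"signed"`` runs on the full connectome including negative weights
        (as originally published); ``"positive_only"`` zeroes negative
        Fisher-z values first.
    """

    def __init__(
        self,
        connectomes: Mapping[str, Connectome],
        cohort: CohortTable,
        spec: ModelSpec,
        polarity: str = "positive",
        weight_mode: str = "signed",
        p_threshold: float = 0.01,
        min_train: int = MIN_TRAIN,
    ) -> None:
        if polarity not in ("positive", "negative", "combined"):
            raise ValueError("polarity must be 'positive', 'negative' or 'combined'")
        if weight_mode not in ("signed", "positive_only"):
            raise ValueError("weight_mode must be 'signed' or 'positive_only'")
        self.spec = spec
        self.cohort = cohort
        self.polarity = polarity
        self.weight_mode = weight_mode
        self.p_threshold = p_threshold
        self.min_train = min_train
        edges = edge_matrix(connectomes)
        if weight_mode == "positive_only":
            edges = edges.clip(lower=0.0)
        common = edges.index.intersection(cohort.subjects)
        y_raw = cohort.target(spec.target_symptom, spec.target_timepoint).loc[common]
        C = cohort.data.loc[common, spec.covariate_columns].astype(float)
        ok = y_raw.notna() & C.notna().all(axis=1)
        self.subjects_ = common[ok.to_numpy()]
        self.edges_ = edges.loc[self.subjects_]
        self.y_ = spec.apply_transform(y_raw.loc[self.subjects_].to_numpy())
        self.C_ = C.loc[self.subjects_].to_numpy()
        self._connectomes = dict(connectomes)

    # -- shared internal API (mirrors GraphPredictiveModel) ---------------

    def _cv(self, y: np.ndarray, folds, use_brain: bool):
        n = y.size
        E = self.edges_.to_numpy(dtype=float)
        pred = np.full(n, np.nan)
        fold_of = np.full(n, -1, dtype=int)
        selected: list[dict] = []
        base = np.column_stack([np.ones(n), self.C_])
        if self.polarity == "combined":
            wanted_signs = [1, -1]
        else:
            wanted_signs = [1] if self.polarity == "positive" else [-1]
        for f, (train, test) in enumerate(folds):
            if train.size < self.min_train:
                raise ValueError(
                    f"fold {f}: {train.size} training cases < minimum {self.min_train}"
                )
            design = base
            info: dict = {"n_edges": 0, "fallback": True}
            if use_brain:
                r, p = _edge_correlations(E, y, train)
                hit = (p < self.p_threshold) & ~np.isnan(r)
                strengths, n_edges = [], 0
                for sign in wanted_signs:
                    cols = np.flatnonzero(hit & ((r > 0) if sign > 0 else (r < 0)))
                    if cols.size:
                        strengths.append(E[:, cols].sum(axis=1))
                        n_edges += int(cols.size)
                if strengths:
                    design = np.column_stack([base, *strengths])
                    info = {"n_edges": n_edges, "fallback": False}
                else:
                    logger.info("fold %d: no edges at p<%g; covariates-only fallback",
                                f, self.p_threshold)
            selected.append(info)
            pred[test] = _ols_predict(design[train], y[train], design[test])
            fold_of[test] = f
        return pred, fold_of, selected

    def _cv_single(self, train, test, use_brain):
        pred, fold_of, selected = self._cv(self.y_, [(train, test)], use_brain)
        return pred[test], fold_of, selected

    def restrict(self, subjects) -> "ConnectomePredictiveModel":
        sub = pd.Index(subjects)
        keep = {s: c for s, c in self._connectomes.items() if s in sub}
        return ConnectomePredictiveModel(
            keep, self.cohort, self.spec, self.polarity, self.weight_mode,
            self.p_threshold, self.min_train,
        )

    # -- public fitting API ----------------------------------------------

    def fit(self, scheme=LOOCV()) -> PredictionResult:
        """Cross-validated CPM: in-fold edge selection + network strength
        in the same covariate-adjusted regression as the GPM.  Folds in
        which no edge passes the threshold fall back to the covariates-only
        model (recorded in ``selected``)."""
        return self._fit(scheme, use_brain=True, label=f"cpm-{self.polarity}")

    def fit_null(self, scheme=LOOCV()) -> PredictionResult:
        return self._fit(scheme, use_brain=False, label="null")

    def _fit(self, scheme, use_brain: bool, label: str) -> PredictionResult:
        if self.subjects_.size < MIN_TRAIN:
            raise ValueError(
                f"{self.subjects_.size} complete cases; need >= {MIN_TRAIN}"
            )
        folds = scheme.folds(self.y_.size)
        pred, fold_of, selected = self._cv(self.y_, folds, use_brain)
        result = PredictionResult(
            subject_ids=np.asarray(self.subjects_),
            observed=self.y_.copy(),
            predicted=pred,
            fold=fold_of,
            selected=selected,
            scheme=scheme.describe(),
            model=label,
        )
        result._pipeline = _CVPipeline(self, folds, use_brain)
        return result

    def compare_to_null(self, k: int = 10, repeats: int = 10, seed: int = 0) -> ComparisonResult:
        return compare_cv(self, self, k=k, repeats=repeats, seed=seed,
                          use_brain=(True, False),
                          labels=(f"cpm-{self.polarity}", "null"))
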