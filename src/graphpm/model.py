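"""Graph-theoretical predictive modeling (GPM).

The GPM predicts a clinical symptom score from a *single* graph-metric
feature chosen inside each cross-validation training fold ("winner take
all"): the candidate metric most strongly correlated with the (transformed)
target over the training subjects enters a multiple regression together
with the covariates (other baseline symptoms and medication load), and the
fitted model predicts the held-out subjects.  Covariates are *not* used in
the selection step, only in model building.

The module follows a model/results design: build a
:class:`GraphPredictiveModel` from a feature table, a cohort table and a
:class:`~graphpm.cohort.ModelSpec`; ``fit`` / ``fit_null`` /
``fit_transfer`` / ``fit_elastic_net`` return :class:`PredictionResult`
objects carrying per-subject predictions, per-fold selections, MSE and
Pearson r, with ``summary()`` and ``permutation_test()`` attached;
``compare_to_null`` and the module-level :func:`compare_cv` return
:class:`~graphpm.validation.ComparisonResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold as _SKKFold

from .cohort import CohortTable, ModelSpec, assemble_features
from .validation import (
    ComparisonResult,
    PermutationResult,
    corrected_cv_ttest,
    mse,
    pearson_prediction_r,
    permutation_test,
)

__all__ = [
    "LOOCV",
    "RepeatedKFold",
    "select_feature",
    "fit_gpm",
    "PredictionResult",
    "GraphPredictiveModel",
    "compare_cv",
]

MIN_TRAIN = 10  # minimum complete training cases per fold


# ---------------------------------------------------------------------------
# Cross-validation schemes


@dataclass(frozen=True)
class LOOCV:
    """Leave-one-out cross-validation: each subject predicted by a model
    trained on all others."""

    def folds(self, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]

    def describe(self) -> str:
        return "LOOCV"


@dataclass(frozen=True)
class RepeatedKFold:
    """k-fold cross-validation, optionally repeated with reshuffled folds."""

    k: int = 10
    repeats: int = 1
    seed: int = 0

    def folds(self, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for rep in range(self.repeats):
            kf = _SKKFold(n_splits=self.k, shuffle=True, random_state=self.seed + rep)
            out.extend((tr, te) for tr, te in kf.split(np.arange(n)))
        return out

    def describe(self) -> str:
        return f"{self.k}-fold x {self.repeats} (seed={self.seed})"


# ---------------------------------------------------------------------------
# Elemental operations


def _train_correlations(X: np.ndarray, y: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pearson r of every feature column with y over the training rows;
    NaN for zero-variance columns."""
    Xt = X[train]
    yt = y[train]
    Xc = Xt - Xt.mean(axis=0)
    yc = yt - yt.mean()
    xnorm = np.sqrt((Xc**2).sum(axis=0))
    ynorm = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (xnorm * ynorm)
    r[xnorm == 0] = np.nan
    if ynorm == 0:
        r[:] = np.nan
    return r


def select_feature(
    features: pd.DataFrame,
    target: Sequence[float],
    training_index: Sequence[int],
    selection: str = "abs",
) -> tuple[str, float]:
    """Winner-take-all feature selection on training subjects only.

    Returns the feature name maximising the selection criterion
    (``"abs"``: |Pearson r|; ``"signed"``: r) together with its training
    correlation.  Ties break toward the canonical (earlier) column; columns
    with zero training variance are skipped.
    """
    train = np.asarray(training_index)
    if train.size < 3:
        raise ValueError("need at least 3 training subjects for selection")
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    r = _train_correlations(X, y, train)
    score = np.abs(r) if selection == "abs" else r
    score = np.where(np.isnan(score), -np.inf, score)
    if not np.any(np.isfinite(score)):
        raise ValueError("all candidate features have zero training variance")
    j = int(np.argmax(score))  # argmax takes the first maximum: canonical tie-break
    return str(features.columns[j]), float(r[j])


def fit_gpm(
    feature: Sequence[float],
    target: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
) -> pd.Series:
    """Ordinary least squares of the target on [brain feature, covariates].

    Returns named coefficients (``intercept``, ``brain``, covariates).
    Raises on rank deficiency, naming the collinear columns.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(target, dtype=float)
    names = ["intercept", "brain"]
    cols = [np.ones_like(y), x]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if isinstance(covariates, pd.DataFrame):
            cnames = list(covariates.columns)
        else:
            cnames = list(covariate_names or [f"cov{i}" for i in range(C.shape[1])])
        names += cnames
        cols += [C[:, i] for i in range(C.shape[1])]
    design = np.column_stack(cols)
    p = design.shape[1]
    if y.size < p + 1:
        raise ValueError(f"need >= {p + 1} complete cases for {p} coefficients")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return pd.Series(beta, index=names, name="coef")


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns whose removal restores full rank (QR pivot diagnostics)."""
    from scipy.linalg import qr

    _, R, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    dependent = piv[np.flatnonzero(diag < tol)]
    # columns beyond the numerical rank are also dependent
    rank = int((diag >= tol).sum())
    dependent = set(dependent.tolist()) | set(piv[rank:].tolist())
    return sorted(names[j] for j in dependent)


def _ols_predict(design_train, y_train, design_test) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design_train, y_train, rcond=None)
    return design_test @ beta


# ---------------------------------------------------------------------------
# Results


@dataclass
class PredictionResult:
    """Cross-validated (or transfer) predictions for one model.

    Observed and predicted scores are on the *modeling* scale (after the
    spec's transform, if any).  ``selected`` records, per fold, the chosen
    feature and its training-fold selection correlation (or the chosen
    (alpha, lambda) for the elastic-net variant).
    """

    subject_ids: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    fold: np.ndarray
    selected: list[dict]
    scheme: str
    model: str = "gpm"
    permutation: PermutationResult | None = None
    _pipeline: object = field(default=None, repr=False)

    @property
    def n_used(self) -> int:
        return int(self.subject_ids.size)

    @property
    def mse(self) -> float:
        return mse(self.observed, self.predicted)

    @property
    def pearson_r(self) -> float:
        return pearson_prediction_r(self.observed, self.predicted)

    @property
    def permutation_p(self) -> float | None:
        return None if self.permutation is None else self.permutation.p

    def selected_counts(self) -> pd.Series:
        names = [s.get("feature") for s in self.selected if "feature" in s]
        return pd.Series(names).value_counts()

    def permutation_test(self, n_perm: int = 10_000, seed: int | None = None) -> PermutationResult:
        """Shuffle targets among included subjects and re-run the full
        prediction pipeline ``n_perm`` times; stores and returns the result."""
        if self._pipeline is None:
            raise ValueError("this result does not carry a re-runnable pipeline")
        self.permutation = permutation_test(self._pipeline, self.observed, n_perm, seed)
        return self.permutation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "observed": self.observed,
                "predicted": self.predicted,
                "fold": self.fold,
                "selected_feature": [
                    self.selected[f].get("feature", "") if f < len(self.selected) else ""
                    for f in self.fold
                ],
            }
        )

    def plot(self, ax=None):
        """Scatter of predicted vs observed scores on the modeling scale,
        annotated with MSE and Pearson r."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(self.observed, self.predicted, s=18, alpha=0.7,
                   edgecolor="none")
        lo = min(self.observed.min(), self.predicted.min())
        hi = max(self.observed.max(), self.predicted.max())
        ax.plot([lo, hi], [lo, hi], ls="--", lw=1, color="grey")
        ax.set_xlabel("observed score")
        ax.set_ylabel("predicted score")
        ax.set_title(
            f"{self.model} ({self.scheme})\n"
            f"r = {self.pearson_r:.3f}, MSE = {self.mse:.3f}, n = {self.n_used}"
        )
        return ax

    def summary(self) -> str:
        lines = [
            f"{self.model.upper()} prediction ({self.scheme})",
            "=" * 40,
            f"n used:     {self.n_used}",
            f"MSE:        {self.mse:.4f}",
            f"Pearson r:  {self.pearson_r:.4f}",
        ]
        if self.permutation is not None:
            lines.append(
                f"permutation p: {self.permutation.p:.4g} "
                f"({self.permutation.n_perm} permutations)"
            )
        counts = self.selected_counts()
        if len(counts):
            top = ", ".join(f"{k} ({v})" for k, v in counts.head(3).items())
            lines.append(f"selected features (top): {top}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The model


class GraphPredictiveModel:
    """GPM for one prediction problem.

    Parameters
    ----------
    features :
        Subjects x candidate graph-metric features (columns
        ``"<state>:<metric>"``), e.g. from
        :func:`~graphpm.cohort.assemble_features`.
    cohort :
        Clinical table with targets, covariates and group labels.
    spec :
        Target, transform, covariates and selection rule.

    Complete cases (non-missing target, covariates and all candidate
    features) are determined once per model — pairwise deletion, so each
    fitted model has its own N.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        cohort: CohortTable,
        spec: ModelSpec,
        min_train: int = MIN_TRAIN,
    ) -> None:
        self.spec = spec
        self.cohort = cohort
        self.min_train = min_train
        common = features.index.intersection(cohort.subjects)
        feats = features.loc[common]
        y_raw = cohort.target(spec.target_symptom, spec.target_timepoint).loc[common]
        C = cohort.data.loc[common, spec.covariate_columns].astype(float)
        ok = (
            feats.notna().all(axis=1)
            & y_raw.notna()
            & C.notna().all(axis=1)
        )
        self.subjects_ = common[ok.to_numpy()]
        self.features_ = feats.loc[self.subjects_]
        self.y_ = spec.apply_transform(y_raw.loc[self.subjects_].to_numpy())
        self.C_ = C.loc[self.subjects_].to_numpy()
        self.covariate_names_ = list(C.columns)

    @classmethod
    def from_metric_vectors(
        cls,
        metric_vectors: Iterable,
        cohort: CohortTable,
        spec: ModelSpec,
        **kw,
    ) -> "GraphPredictiveModel":
        return cls(assemble_features(metric_vectors, spec), cohort, spec, **kw)

    # -- internal fold machinery (shared by fit / null / permutations) ----

    def _design(self, x: np.ndarray | None) -> np.ndarray:
        n = self.y_.size
        if x is None:
            return np.column_stack([np.ones(n), self.C_])
        return np.column_stack([np.ones(n), x, self.C_])

    def _cv(self, y: np.ndarray, folds, use_brain: bool):
        n = y.size
        X = self.features_.to_numpy(dtype=float)
        cols = list(self.features_.columns)
        pred = np.full(n, np.nan)
        fold_of = np.full(n, -1, dtype=int)
        selected: list[dict] = []
        base = np.column_stack([np.ones(n), self.C_])
        for f, (train, test) in enumerate(folds):
            if train.size < self.min_train:
                raise ValueError(
                    f"fold {f}: {train.size} training cases < minimum {self.min_train}"
                )
            if use_brain:
                r = _train_correlations(X, y, train)
                score = np.abs(r) if self.spec.selection == "abs" else r
                score = np.where(np.isnan(score), -np.inf, score)
                if not np.any(np.isfinite(score)):
                    raise ValueError("all candidate features have zero training variance")
                j = int(np.argmax(score))
                design = np.column_stack([base, X[:, j]])
                selected.append({"feature": cols[j], "r_train": float(r[j])})
            else:
                design = base
                selected.append({})
            pred[test] = _ols_predict(design[train], y[train], design[test])
            fold_of[test] = f
        return pred, fold_of, selected

    def _check_size(self, scheme) -> None:
        if self.subjects_.size < MIN_TRAIN:
            raise ValueError(
                f"{self.subjects_.size} complete cases; need >= {MIN_TRAIN}"
            )

    # -- public fitting API ----------------------------------------------

    def fit(self, scheme=LOOCV()) -> PredictionResult:
        """Cross-validated GPM: in-fold selection + covariate-adjusted OLS."""
        return self._fit(scheme, use_brain=True, label="gpm")

    def fit_null(self, scheme=LOOCV()) -> PredictionResult:
        """The corresponding null model: covariates only, same CV machinery."""
        return self._fit(scheme, use_brain=False, label="null")

    def _fit(self, scheme, use_brain: bool, label: str) -> PredictionResult:
        self._check_size(scheme)
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

    def fit_transfer(self, train_group: str, test_group: str) -> PredictionResult:
        """Train once on one diagnostic group, predict the other.

        A single selection + fit on all training-group subjects; MSE and r
        are computed on the test group only.  The companion null model is
        available via ``fit_transfer_null``.
        """
        return self._transfer(train_group, test_group, use_brain=True)

    def fit_transfer_null(self, train_group: str, test_group: str) -> PredictionResult:
        return self._transfer(train_group, test_group, use_brain=False)

    def _transfer(self, train_group, test_group, use_brain: bool) -> PredictionResult:
        groups = self.cohort.groups().loc[self.subjects_]
        for g in (train_group, test_group):
            if not (groups == g).any():
                raise ValueError(f"group {g!r} has no complete cases")
        train = np.flatnonzero((groups == train_group).to_numpy())
        test = np.flatnonzero((groups == test_group).to_numpy())
        pred, _, selected = self._cv_single(train, test, use_brain)
        return PredictionResult(
            subject_ids=np.asarray(self.subjects_[test]),
            observed=self.y_[test],
            predicted=pred,
            fold=np.zeros(test.size, dtype=int),
            selected=selected,
            scheme=f"transfer {train_group}->{test_group}",
            model="gpm" if use_brain else "null",
        )

    def _cv_single(self, train, test, use_brain):
        pred, fold_of, selected = self._cv_on_folds([(train, test)], use_brain)
        return pred[test], fold_of, selected

    def _cv_on_folds(self, folds, use_brain):
        return self._cv(self.y_, folds, use_brain)

    def restrict(self, subjects) -> "GraphPredictiveModel":
        """Copy of this model restricted to the given subjects (for paired
        comparisons on identical complete-case sets)."""
        sub = pd.Index(subjects)
        return GraphPredictiveModel(
            self.features_.loc[self.features_.index.intersection(sub)],
            self.cohort,
            self.spec,
            self.min_train,
        )

    def compare_to_null(
        self, k: int = 10, repeats: int = 10, seed: int = 0
    ) -> ComparisonResult:
        """Corrected repeated k-fold CV test of GPM vs its null model."""
        return compare_cv(self, self, k=k, repeats=repeats, seed=seed,
                          use_brain=(True, False), labels=("gpm", "null"))

    # -- elastic-net variant ---------------------------------------------

    def fit_elastic_net(
        self,
        scheme=LOOCV(),
        alpha_grid: np.ndarray | None = None,
        n_lambda: int = 20,
        inner_folds: int = 5,
        inner_seed: int = 0,
        lambda_grid: np.ndarray | None = None,
    ) -> PredictionResult:
        """Elastic-net GPM: all candidate metrics enter, regularised.

        Within each outer training fold, features are standardised and the
        covariates partialled out (Frisch-Waugh), so covariates stay
        unpenalised; an inner CV over the alpha grid (0 to 1 in steps of
        0.05 by default, 21 values) x a geometric lambda path picks the
        (alpha, lambda) pair minimising inner CV error, which is then refit
        and used to predict the held-out subjects.
        """
        from ._elasticnet import elastic_net_cv

        self._check_size(scheme)
        if alpha_grid is None:
            alpha_grid = np.round(np.arange(0, 1.0001, 0.05), 2)
        folds = scheme.folds(self.y_.size)
        pred, fold_of, selected = elastic_net_cv(
            self.features_.to_numpy(dtype=float),
            self.y_,
            self.C_,
            folds,
            alpha_grid=np.asarray(alpha_grid, dtype=float),
            n_lambda=n_lambda,
            inner_folds=inner_folds,
            inner_seed=inner_seed,
            lambda_grid=lambda_grid,
            feature_names=list(self.features_.columns),
            min_train=self.min_train,
        )
        return PredictionResult(
            subject_ids=np.asarray(self.subjects_),
            observed=self.y_.copy(),
            predicted=pred,
            fold=fold_of,
            selected=selected,
            scheme=scheme.describe(),
            model="gpm-enet",
        )


class _CVPipeline:
    """Re-runnable CV pipeline for permutation testing (targets shuffled,
    covariates and features fixed to their subjects)."""

    def __init__(self, model: GraphPredictiveModel, folds, use_brain: bool):
        self.model = model
        self.folds = folds
        self.use_brain = use_brain

    def __call__(self, y: np.ndarray) -> float:
        pred, _, _ = self.model._cv(np.asarray(y, dtype=float), self.folds, self.use_brain)
        return pearson_prediction_r(y, pred)


# ---------------------------------------------------------------------------
# Paired model comparison


def compare_cv(
    model_a,
    model_b,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    use_brain: tuple[bool, bool] = (True, True),
    labels: tuple[str, str] = ("model", "null"),
) -> ComparisonResult:
    """Corrected repeated k-fold CV comparison of two models.

    Both models are evaluated on identical fold assignments over the
    intersection of their complete-case subject sets; the per-fold test-set
    MSE difference (B minus A, so positive favours A) feeds the corrected
    resampled t-test.
    """
    subjects = (
        pd.Index(model_a.subjects_).intersection(pd.Index(model_b.subjects_)).sort_values()
    )
    a = model_a.restrict(subjects)
    b = model_b.restrict(subjects)
    if not np.array_equal(np.asarray(a.subjects_), np.asarray(b.subjects_)):
        raise ValueError("models could not be aligned on a shared subject set")
    n = len(subjects)
    scheme = RepeatedKFold(k=k, repeats=repeats, seed=seed)
    folds = scheme.folds(n)
    diffs = []
    se_a = np.zeros(n)
    se_b = np.zeros(n)
    for train, test in folds:
        pa, _, _ = a._cv_single(train, test, use_brain[0])
        pb, _, _ = b._cv_single(train, test, use_brain[1])
        ya = a.y_[test]
        yb = b.y_[test]
        la = float(np.mean((ya - pa) ** 2))
        lb = float(np.mean((yb - pb) ** 2))
        diffs.append(lb - la)
        se_a[test] += (ya - pa) ** 2 / repeats
        se_b[test] += (yb - pb) ** 2 / repeats
    n_test = int(round(n / k))
    n_train = n - n_test
    t, p, df = corrected_cv_ttest(np.asarray(diffs), n_train, n_test)
    return ComparisonResult(
        mse_model=float(se_a.mean()),
        mse_null=float(se_b.mean()),
        t=t,
        p=p,
        df=df,
        k=k,
        repeats=repeats,
        n_train=n_train,
        n_test=n_test,
        fold_diffs=np.asarray(diffs),
        label_model=labels[0],
        label_null=labels[1],
    )
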