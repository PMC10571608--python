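"""Model evaluation and comparison statistics.

Covers the quantities used to judge cross-validated symptom prediction:
mean squared error (MSE) and its relative difference against a null model,
Pearson correlation of predicted vs observed scores, permutation inference
for that correlation, and the corrected repeated k-fold CV t-test for
paired model comparison.

The corrected test addresses the optimism of a naive paired t-test on
per-fold losses: because training sets overlap heavily across folds and
repeats, fold-level loss differences are positively correlated and the
plain variance estimate is too small.  The Nadeau-Bengio correction
inflates the variance by ``(1/J + n_test/n_train)`` (J = folds x repeats)
instead of ``1/J`` alone, restoring approximately nominal type-I error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "mse",
    "mse_relative_difference",
    "pearson_prediction_r",
    "corrected_cv_ttest",
    "permutation_test",
    "PermutationResult",
    "ComparisonResult",
]

DEFAULT_N_PERM = 10_000


def mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared difference over complete (non-missing) pairs."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = np.isfinite(observed) & np.isfinite(predicted)
    if not ok.any():
        raise ValueError("no complete observed/predicted pairs")
    return float(np.mean((observed[ok] - predicted[ok]) ** 2))


def mse_relative_difference(mse_null: float, mse_model: float) -> float:
    """Relative MSE improvement of a model over its null:
    ``(MSE_null - MSE_model) / MSE_null``.  Positive values mean the model
    beats the null."""
    if mse_null <= 0:
        raise ValueError("mse_null must be positive")
    return (mse_null - mse_model) / mse_null


def pearson_prediction_r(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between predicted and observed scores."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ok = np.isfinite(observed) & np.isfinite(predicted)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    o, p = observed[ok], predicted[ok]
    if o.std() == 0 or p.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(o, p).statistic)


def corrected_cv_ttest(
    error_diffs: np.ndarray,
    n_train: int,
    n_test: int,
    correction: bool = True,
) -> tuple[float, float, int]:
    """Corrected resampled t-test on per-fold loss differences.

    Parameters
    ----------
    error_diffs : array, length J = k x repeats
        Per-fold difference in mean squared error between two models
        evaluated on identical folds.
    n_train, n_test : int
        Typical training and test fold sizes.
    correction : bool
        With the correction the variance factor is ``1/J + n_test/n_train``
        (Nadeau-Bengio); without it, ``1/J`` (the anti-conservative plain
        resampled t, kept for demonstration).

    Returns
    -------
    (t, p, df) with ``df = J - 1`` and a two-sided p-value.
    """
    d = np.asarray(error_diffs, dtype=float)
    J = d.size
    if J < 2:
        raise ValueError("need at least 2 fold-level differences")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("fold sizes must be positive")
    m = d.mean()
    v = d.var(ddof=1)
    df = J - 1
    factor = 1.0 / J + (n_test / n_train if correction else 0.0)
    if v == 0:
        if m == 0:
            return 0.0, 1.0, df
        warnings.warn("zero variance with nonzero mean difference", RuntimeWarning)
        return float(np.sign(m) * np.inf), float(np.finfo(float).tiny), df
    t = m / np.sqrt(factor * v)
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


@dataclass
class PermutationResult:
    """One-sided permutation test of a prediction correlation."""

    r_observed: float
    p: float
    null_distribution: np.ndarray
    n_perm: int

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PermutationResult(r={self.r_observed:.3f}, p={self.p:.4g}, "
            f"n_perm={self.n_perm})"
        )


def permutation_test(
    pipeline: Callable[[np.ndarray], float],
    target: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation inference for a cross-validated prediction correlation.

    ``pipeline(y)`` must re-run the full prediction procedure with target
    vector ``y`` (subjects fixed, covariates travelling with the subject)
    and return the predicted-observed Pearson r.  Targets are shuffled
    among included subjects; the one-sided p-value uses the add-one rule
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    y = np.asarray(target, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("constant target: permutation test degenerate")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives coarse p-values", UserWarning)
    rng = np.random.default_rng(seed)
    r_obs = pipeline(y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = pipeline(rng.permutation(y))
    p = (1 + np.sum(null >= r_obs)) / (1 + n_perm)
    return PermutationResult(float(r_obs), float(p), null, n_perm)


@dataclass
class ComparisonResult:
    """Paired comparison of two cross-validated models on identical folds."""

    mse_model: float
    mse_null: float
    t: float
    p: float
    df: int
    k: int
    repeats: int
    n_train: int
    n_test: int
    fold_diffs: np.ndarray = field(repr=False, default=None)
    label_model: str = "model"
    label_null: str = "null"

    @property
    def mse_diff(self) -> float:
        """Relative MSE improvement, ``(MSE_null - MSE_model)/MSE_null``."""
        return mse_relative_difference(self.mse_null, self.mse_model)

    def summary(self) -> str:
        lines = [
            "Model comparison (corrected repeated k-fold CV test)",
            "=" * 52,
            f"MSE ({self.label_model}):      {self.mse_model:.4f}",
            f"MSE ({self.label_null}):       {self.mse_null:.4f}",
            f"MSE_diff:          {100 * self.mse_diff:.2f}%",
            f"t = {self.t:.3f}, df = {self.df}, p = {self.p:.4g}",
            f"scheme: k={self.k} x repeats={self.repeats} "
            f"(n_train~{self.n_train}, n_test~{self.n_test})",
        ]
        return "\n".join(lines)
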