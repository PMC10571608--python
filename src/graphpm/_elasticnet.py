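"""Elastic-net variant of the GPM: nested CV over an (alpha, lambda) grid.

Instead of winner-take-all selection, all candidate graph metrics enter a
regularised regression.  Covariates stay unpenalised via Frisch-Waugh
partialling: within each outer training fold the covariates are regressed
out of the target and of every (standardised) feature, the elastic net is
fitted on the residuals, and the covariate fit is added back at prediction
time.  The alpha grid (mixing parameter: 0 = ridge, 1 = lasso) and a
geometric lambda path (overall penalty strength) are searched by inner CV;
the (alpha, lambda) pair minimising inner CV error wins.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int) -> np.ndarray:
    """Geometric path from the smallest lambda that zeroes all coefficients.

    sklearn's automatic path rejects l1_ratio = 0, so the path is anchored
    at ``max|X'y| / (n * max(alpha, 0.05))`` and spans three decades.
    """
    n = y.size
    lam_max = np.abs(X.T @ y).max() / (n * max(alpha, 0.05))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def _partial_out(C1: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Regress covariates (with intercept) out of y and each column of X."""
    gy, *_ = np.linalg.lstsq(C1, y, rcond=None)
    gX, *_ = np.linalg.lstsq(C1, X, rcond=None)
    return y - C1 @ gy, X - C1 @ gX, gy, gX


def elastic_net_cv(
    X: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    folds,
    alpha_grid: np.ndarray,
    n_lambda: int = 20,
    inner_folds: int = 5,
    inner_seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    min_train: int = 10,
):
    """Outer-CV predictions with inner-CV hyper-parameter choice.

    Returns ``(predictions, fold_of, selected)`` where ``selected`` records
    per outer fold the winning (alpha, lambda) and the nonzero features.
    """
    n, p = X.shape
    names = feature_names or [f"f{j}" for j in range(p)]
    pred = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    selected: list[dict] = []
    for f, (train, test) in enumerate(folds):
        if train.size < max(min_train, inner_folds):
            raise ValueError(
                f"outer fold {f}: {train.size} training cases too few for inner CV"
            )
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        C1 = np.column_stack([np.ones(n), C])
        yr_tr, Xr_tr, gy, gX = _partial_out(C1[train], y[train], Xs[train])
        Xr_te = Xs[test] - C1[test] @ gX
        cov_te = C1[test] @ gy

        alpha, lam, enet = _inner_select(
            Xr_tr, yr_tr, alpha_grid, n_lambda, inner_folds, inner_seed, lambda_grid
        )
        pred[test] = cov_te + enet.predict(Xr_te)
        fold_of[test] = f
        nonzero = [names[j] for j in np.flatnonzero(enet.coef_ != 0)]
        selected.append({"alpha": float(alpha), "lambda": float(lam), "nonzero": nonzero})
    return pred, fold_of, selected


def _inner_select(Xr, yr, alpha_grid, n_lambda, inner_folds, inner_seed, lambda_grid):
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed)
    splits = list(kf.split(Xr))
    best = (np.inf, None, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)  # l1_ratio = 0 advisory
        for alpha in alpha_grid:
            lams = (
                np.asarray(lambda_grid, dtype=float)
                if lambda_grid is not None
                else _lambda_path(Xr, yr, alpha, n_lambda)
            )
            for lam in lams:
                err = 0.0
                for itr, ite in splits:
                    m = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                                   max_iter=2000)
                    m.fit(Xr[itr], yr[itr])
                    err += float(np.mean((yr[ite] - m.predict(Xr[ite])) ** 2))
                err /= len(splits)
                if err < best[0]:
                    best = (err, float(alpha), float(lam))
        _, alpha, lam = best
        final = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=5000)
        final.fit(Xr, yr)
    return alpha, lam, final
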