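"""Consensus feature selection over the combined proteomic + clinical matrix.

Five selectors — absolute Pearson correlation, chi-square score on min-max
scaled features, recursive feature elimination with a logistic base
estimator, L1-penalized logistic regression, and random-forest impurity
importance — each nominate at most 20 variables; a variable enters the model
when at least 4 of the 5 selectors agree on it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, chi2
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import MinMaxScaler, StandardScaler

__all__ = ["METHODS", "select_per_method", "select_features", "consensus"]

METHODS = ("pearson", "chi2", "rfe", "logistic_l1", "random_forest")


def _as_binary(labels) -> np.ndarray:
    y = pd.Series(labels)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {classes}")
    return (y == classes[1]).to_numpy(dtype=int)


def _constant_mask(X: pd.DataFrame) -> pd.Series:
    const = X.std(ddof=0) == 0
    if const.any():
        warnings.warn(
            f"constant features excluded from ranking: {list(X.columns[const])}",
            stacklevel=3,
        )
    return const


def _rank_from_scores(scores: pd.Series) -> pd.Series:
    """Dense 1-based ranks, best first; ties broken by feature name."""
    order = sorted(scores.index, key=lambda f: (-scores[f], str(f)))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(scores.index)


def _method_scores(
    X: pd.DataFrame, y: np.ndarray, method: str, seed: int, alpha: float = 0.05
) -> tuple[pd.Series, pd.Series]:
    """Per-feature score and eligibility mask for a score-based selector.

    The cap alone would make every selector fill its quota even on pure
    noise, so scorers with a calibrated notion of relevance also gate: the
    correlation selector keeps features significant at two-sided p < alpha
    (unadjusted), and the forest selector requires an importance above the
    95th percentile of importances from a single label-permuted refit.  The
    chi-square statistic on min-max-scaled continuous features has no
    properly calibrated p-value, so it stays a pure capped ranking.
    """
    if method == "pearson":
        r = np.zeros(X.shape[1])
        p = np.ones(X.shape[1])
        for j, col in enumerate(X.columns):
            r[j], p[j] = stats.pearsonr(X[col], y)
        return (
            pd.Series(np.abs(r), index=X.columns),
            pd.Series(p < alpha, index=X.columns),
        )
    if method == "chi2":
        Xs = MinMaxScaler().fit_transform(X)
        stat, _ = chi2(Xs, y)
        return (
            pd.Series(np.nan_to_num(stat), index=X.columns),
            pd.Series(True, index=X.columns),
        )
    if method == "random_forest":
        rf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
        rf.fit(X, y)
        imp = pd.Series(rf.feature_importances_, index=X.columns)
        rng = np.random.default_rng(seed)
        null_rf = RandomForestClassifier(
            n_estimators=500, random_state=seed + 1, n_jobs=1
        )
        null_rf.fit(X, rng.permutation(y))
        threshold = float(np.percentile(null_rf.feature_importances_, 95))
        return imp, imp > threshold
    raise KeyError(method)


def select_per_method(
    X: pd.DataFrame,
    labels,
    method: str,
    cap: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Boolean selection vector (indexed like ``X.columns``) for one selector.

    Score-based selectors keep the ``cap`` best-scoring variables among
    those passing the method's own relevance gate (see
    :func:`_method_scores`); without the gate every selector would fill its
    quota even on pure noise and the 4-of-5 consensus would lose all
    specificity.  RFE
    eliminates one variable per step with an L2-logistic base estimator until
    ``cap`` remain.  The L1-logistic selector keeps nonzero coefficients at a
    regularization strength chosen by 5-fold cross-validation, truncated to
    ``cap`` by absolute coefficient.  Constant features are excluded from
    every ranking with a warning.  Deterministic given ``seed``.
    """
    if method not in METHODS:
        raise KeyError(f"unknown selection method {method!r}")
    y = _as_binary(labels)
    selected = pd.Series(False, index=X.columns)
    if cap <= 0:
        return selected
    const = _constant_mask(X)
    # canonical column order: estimators with feature subsampling (forest,
    # CV folds) are otherwise sensitive to the caller's column order
    Xv = X.loc[:, ~const]
    Xv = Xv[sorted(Xv.columns, key=str)]
    if Xv.shape[1] == 0:
        return selected

    if method in ("pearson", "chi2", "random_forest"):
        scores, eligible = _method_scores(Xv, y, method, seed)
        ranks = _rank_from_scores(scores)
        selected.loc[ranks.index[(ranks <= cap) & eligible]] = True
        return selected

    Xs = pd.DataFrame(
        StandardScaler().fit_transform(Xv), columns=Xv.columns, index=Xv.index
    )
    if method == "rfe":
        base = LogisticRegression(
            penalty="l2", class_weight="balanced", max_iter=2000, random_state=seed
        )
        rfe = RFE(base, n_features_to_select=min(cap, Xs.shape[1]), step=1)
        rfe.fit(Xs, y)
        selected.loc[Xs.columns[rfe.support_]] = True
        return selected

    # logistic_l1
    lcv = LogisticRegressionCV(
        penalty="l1",
        solver="liblinear",
        Cs=np.logspace(-2, 2, 10),
        cv=5,
        random_state=seed,
        max_iter=2000,
    )
    lcv.fit(Xs, y)
    coef = pd.Series(np.abs(lcv.coef_.ravel()), index=Xs.columns)
    nonzero = coef[coef > 0]
    keep = sorted(nonzero.index, key=lambda f: (-nonzero[f], str(f)))[:cap]
    selected.loc[keep] = True
    return selected


def select_features(
    X: pd.DataFrame,
    labels,
    cap: int = 20,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Run every selector and tabulate the votes.

    Returns the selection grid: one row per variable, one boolean column per
    method, a ``total`` vote count, and a ``mean_rank`` column (mean of each
    score-based method's rank, used only to order the consensus list).
    """
    grid = pd.DataFrame(index=X.columns)
    rank_cols = []
    y = _as_binary(labels)
    const = _constant_mask(X)
    Xv = X.loc[:, ~const]
    Xv = Xv[sorted(Xv.columns, key=str)]
    for method in methods:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid[method] = select_per_method(X, labels, method, cap=cap, seed=seed)
        if method in ("pearson", "chi2", "random_forest") and Xv.shape[1]:
            scores, _ = _method_scores(Xv, y, method, seed)
            rank_cols.append(_rank_from_scores(scores).reindex(X.columns))
    grid["total"] = grid[list(methods)].sum(axis=1).astype(int)
    grid["mean_rank"] = (
        pd.concat(rank_cols, axis=1).mean(axis=1)
        if rank_cols
        else pd.Series(np.nan, index=X.columns)
    )
    return grid


def consensus(selection: pd.DataFrame, min_votes: int = 4) -> list[str]:
    """Variables selected by at least ``min_votes`` methods.

    Accepts a grid from :func:`select_features` or any boolean
    variables-by-methods frame (``total``/``mean_rank`` columns are derived
    when absent).  Ordered by vote count (descending), then mean rank across
    score-based methods (ascending) when available, then variable name — so
    the output never depends on the input row order.
    """
    grid = selection.copy()
    method_cols = [c for c in grid.columns if c not in ("total", "mean_rank")]
    if "total" not in grid.columns:
        grid["total"] = grid[method_cols].astype(bool).sum(axis=1).astype(int)
    if "mean_rank" not in grid.columns:
        grid["mean_rank"] = np.nan
    grid["_name"] = grid.index.astype(str)
    kept = grid[grid["total"] >= min_votes]
    kept = kept.sort_values(
        by=["total", "mean_rank", "_name"],
        ascending=[False, True, True],
        na_position="last",
        kind="stable",
    )
    return list(kept.index)
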