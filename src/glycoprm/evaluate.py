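"""Model training, evaluation, ROC comparison and ensemble voting.

The evaluation protocol mirrors the verification study: 20 diagnostic
grey-zone samples (tPSA in [4, 10] ng/mL) are held out entirely; the
remaining samples are split 70/30 (stratified) into training and test sets;
five classifiers (random forest, logistic regression, KNN, RBF-SVM, decision
tree) are scored on the test set with bootstrap confidence intervals; the
multivariate ROC is compared against the tPSA-only ROC with the fast DeLong
test; and the grey-zone samples are classified by 4-of-5 hard voting and
F1-weighted soft voting of models refit on the full model-building set.
The aggressiveness sub-analysis reruns the protocol within the PCa group
(AG: Gleason > 3+3 vs NAG: 3+3) with four models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SplitSpec",
    "ModelScores",
    "EvaluationReport",
    "split",
    "make_models",
    "train_and_score",
    "delong_compare",
    "hard_vote",
    "soft_vote",
    "greyzone_vote",
    "run_aggressiveness",
    "DEFAULT_MODELS",
    "AGGRESSIVENESS_MODELS",
]

DEFAULT_MODELS = ("random_forest", "logistic", "knn", "svm", "decision_tree")
#: the aggressiveness sub-analysis reports four models (no SVM)
AGGRESSIVENESS_MODELS = ("random_forest", "logistic", "knn", "decision_tree")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out design: grey-zone set plus a stratified train/test split."""

    holdout_greyzone: int = 20
    train_frac: float = 0.70
    greyzone_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.holdout_greyzone < 0:
            raise ValueError("holdout_greyzone must be >= 0")


def split(
    samples: pd.DataFrame,
    spec: SplitSpec | None = None,
    label_col: str = "diagnosis",
    tpsa_col: str = "tpsa",
) -> dict[str, pd.DataFrame]:
    """Partition samples into ``greyzone``, ``train`` and ``test``.

    Grey-zone samples are drawn (seeded, uniformly) from those with tPSA in
    the configured range; the remainder is split stratified by label at
    ``train_frac``.  Raises if fewer eligible samples exist than requested.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.greyzone_range
    eligible = samples.index[(samples[tpsa_col] >= lo) & (samples[tpsa_col] <= hi)]
    if len(eligible) < spec.holdout_greyzone:
        raise ValueError(
            f"only {len(eligible)} samples have {tpsa_col} in [{lo}, {hi}]; "
            f"{spec.holdout_greyzone} requested"
        )
    grey_idx = rng.choice(eligible, size=spec.holdout_greyzone, replace=False)
    grey = samples.loc[grey_idx]
    build = samples.drop(index=grey_idx)
    train, test = train_test_split(
        build,
        train_size=spec.train_frac,
        stratify=build[label_col],
        random_state=spec.seed,
    )
    return {"greyzone": grey, "train": train, "test": test}


def make_models(seed: int = 0, names: tuple[str, ...] = DEFAULT_MODELS) -> dict:
    """Instantiate the classifier set (seeded; scalers where models need them)."""
    zoo = {
        "random_forest": RandomForestClassifier(
            n_estimators=500, random_state=seed, n_jobs=1
        ),
        "logistic": make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed),
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
        "svm": make_pipeline(
            StandardScaler(), SVC(kernel="rbf", probability=True, random_state=seed)
        ),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
    }
    unknown = set(names) - set(zoo)
    if unknown:
        raise KeyError(f"unknown model(s): {sorted(unknown)}")
    return {name: zoo[name] for name in names}


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    """AUC, F1, accuracy, specificity, sensitivity from a 0/1 truth vector."""
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    out = {
        "auc": roc_auc_score(y_true, scores) if len(np.unique(y_true)) == 2 else np.nan,
        "f1": f1_score(y_true, y_pred, zero_division=0),
        "accuracy": (tp + tn) / len(y_true),
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
    }
    return out


def _bootstrap_ci(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    n_boot: int,
    seed: int,
) -> dict[str, tuple[float, float]]:
    """Stratified bootstrap 95% CIs for every metric over the test set."""
    if n_boot <= 0:
        return {}
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    samples: dict[str, list[float]] = {}
    for _ in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = _binary_metrics(y_true[idx], y_pred[idx], scores[idx])
        for k, v in m.items():
            samples.setdefault(k, []).append(v)
    return {
        k: (
            float(np.nanpercentile(v, 2.5)),
            float(np.nanpercentile(v, 97.5)),
        )
        for k, v in samples.items()
    }


@dataclass
class ModelScores:
    """One model's test-set outcome."""

    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]
    scores: np.ndarray  # probability of the positive class per test sample
    predictions: np.ndarray  # 0/1 at the 0.5 cutoff
    confusion: np.ndarray  # 2x2, rows true (neg, pos)
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)


@dataclass
class EvaluationReport:
    """Per-model metrics plus the univariate-baseline ROC comparison."""

    models: dict[str, ModelScores]
    y_test: np.ndarray
    positive_label: str
    feature_importances: pd.Series | None = None
    delong: dict | None = None
    baseline: dict | None = None  # univariate tPSA metrics
    voting: pd.DataFrame | None = None

    def metrics_table(self) -> pd.DataFrame:
        rows = {name: ms.metrics for name, ms in self.models.items()}
        return pd.DataFrame(rows).T


def train_and_score(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: list[str],
    label_col: str = "diagnosis",
    positive_label: str = "PCa",
    model_names: tuple[str, ...] = DEFAULT_MODELS,
    seed: int = 0,
    n_boot: int = 2000,
    baseline_col: str | None = "tpsa",
) -> EvaluationReport:
    """Fit every model on the training split and score the test split.

    Sensitivity is defined with ``positive_label`` as the positive class;
    predictions use the 0.5 probability cutoff; 95% CIs come from a seeded
    stratified bootstrap of the test set (``n_boot`` resamples, 0 disables).
    When ``baseline_col`` is given the report carries the univariate ROC on
    the raw marker values and the DeLong comparison against the best-AUC
    model.
    """
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise KeyError(f"features absent from the matrix: {missing}")
    y_train = (train[label_col] == positive_label).to_numpy(dtype=int)
    y_test = (test[label_col] == positive_label).to_numpy(dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")

    X_train = train[features].to_numpy(dtype=float)
    X_test = test[features].to_numpy(dtype=float)

    models = make_models(seed=seed, names=model_names)
    results: dict[str, ModelScores] = {}
    importances = None
    for name, model in models.items():
        model.fit(X_train, y_train)
        scores = model.predict_proba(X_test)[:, 1]
        preds = (scores >= 0.5).astype(int)
        metrics = _binary_metrics(y_test, preds, scores)
        ci = _bootstrap_ci(y_test, preds, scores, n_boot=n_boot, seed=seed)
        fpr, tpr, _ = roc_curve(y_test, scores)
        results[name] = ModelScores(
            metrics=metrics,
            ci=ci,
            scores=scores,
            predictions=preds,
            confusion=confusion_matrix(y_test, preds, labels=[0, 1]),
            roc=(fpr, tpr),
        )
        if name == "random_forest":
            importances = pd.Series(
                model.feature_importances_, index=features
            ).sort_values(ascending=False)

    report = EvaluationReport(
        models=results,
        y_test=y_test,
        positive_label=positive_label,
        feature_importances=importances,
    )
    if baseline_col is not None and baseline_col in test.columns:
        base_scores = test[baseline_col].to_numpy(dtype=float)
        report.baseline = {
            "marker": baseline_col,
            "auc": float(roc_auc_score(y_test, base_scores)),
        }
        best = max(results, key=lambda n: results[n].metrics["auc"])
        report.delong = {
            "model": best,
            **delong_compare(results[best].scores, base_scores, y_test),
        }
    return report


# ---------------------------------------------------------------------------
# DeLong test for correlated ROC curves
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative).

    V10_i is the fraction of negatives that positive i outranks (ties half);
    V01_j the fraction of positives that negative j is outranked by.  Their
    means equal the Mann-Whitney AUC.  Computed via midranks.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - _midrank(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - _midrank(neg)) / m
    return v10, v01


def delong_compare(scores_a, scores_b, labels) -> dict:
    """Fast DeLong comparison of two correlated ROC AUCs on the same samples.

    Returns ``{"auc_a", "auc_b", "z", "p"}`` with a two-sided p-value from
    the normal approximation.  Degenerate variance (e.g. both score vectors
    identical) yields z = 0, p = 1 when the AUCs agree and NaN with a warning
    otherwise.  Invariant under strictly monotone transforms of either score
    vector (only rank orders enter).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != y.shape:
        raise ValueError("score vectors and labels must share one shape")
    v10a, v01a = _structural_components(scores_a, y)
    v10b, v01b = _structural_components(scores_b, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (
        (np.var(d10, ddof=1) / m if m > 1 else 0.0)
        + (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    )
    delta = auc_a - auc_b
    if var <= 0:
        if np.isclose(delta, 0.0):
            return {"auc_a": auc_a, "auc_b": auc_b, "z": 0.0, "p": 1.0}
        warnings.warn("degenerate DeLong variance; p reported as NaN", stacklevel=2)
        return {"auc_a": auc_a, "auc_b": auc_b, "z": np.nan, "p": np.nan}
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": float(p)}


# ---------------------------------------------------------------------------
# Ensemble voting
# ---------------------------------------------------------------------------


def hard_vote(predictions: dict[str, str] | list[str], positive: str = "PCa"):
    """Majority class over per-model label votes, ties broken positive.

    The tie-break favors the positive (disease) class: in a screening
    context a false negative is costlier than a false positive.  Returns
    ``(class, agreement_count)``.
    """
    votes = list(predictions.values()) if isinstance(predictions, dict) else list(predictions)
    if len(votes) < 2:
        raise ValueError("hard voting needs at least two models")
    n_pos = sum(v == positive for v in votes)
    n_neg = len(votes) - n_pos
    if n_pos >= n_neg:
        return positive, n_pos
    other = next(v for v in votes if v != positive)
    return other, n_neg


def soft_vote(
    predictions: dict[str, str],
    weights: dict[str, float],
    positive: str = "PCa",
) -> str:
    """F1-weighted vote: the class with the larger summed weight wins.

    Ties go to the positive class.  All weights must be non-negative and not
    all zero.
    """
    if set(predictions) != set(weights):
        raise ValueError("predictions and weights must cover the same models")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    total = sum(weights.values())
    if total == 0:
        raise ValueError("all-zero weights")
    w_pos = sum(w for name, w in weights.items() if predictions[name] == positive)
    if w_pos >= total - w_pos:
        return positive
    return next(v for v in predictions.values() if v != positive)


def greyzone_vote(
    build: pd.DataFrame,
    greyzone: pd.DataFrame,
    features: list[str],
    f1_weights: dict[str, float],
    label_col: str = "diagnosis",
    positive_label: str = "PCa",
    negative_label: str = "BPH",
    model_names: tuple[str, ...] = DEFAULT_MODELS,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify the held-out grey-zone samples by hard and soft voting.

    Models are refit on the full model-building set before voting; the soft
    vote weights each model by its test-set F1.  Returns one row per
    grey-zone sample with per-model votes, both ensemble calls and (when the
    true label is present) correctness flags.
    """
    y_build = (build[label_col] == positive_label).to_numpy(dtype=int)
    X_build = build[features].to_numpy(dtype=float)
    X_grey = greyzone[features].to_numpy(dtype=float)
    models = make_models(seed=seed, names=model_names)
    votes: dict[str, list[str]] = {}
    for name, model in models.items():
        model.fit(X_build, y_build)
        preds = (model.predict_proba(X_grey)[:, 1] >= 0.5).astype(int)
        votes[name] = [positive_label if p else negative_label for p in preds]

    rows = []
    for i in range(len(greyzone)):
        per_model = {name: votes[name][i] for name in models}
        hard_cls, agreement = hard_vote(per_model, positive=positive_label)
        soft_cls = soft_vote(per_model, f1_weights, positive=positive_label)
        rows.append({**per_model, "hard_vote": hard_cls, "agreement": agreement,
                     "soft_vote": soft_cls})
    out = pd.DataFrame(rows, index=greyzone.index)
    if label_col in greyzone.columns:
        out["true_label"] = greyzone[label_col].to_numpy()
        out["hard_correct"] = out["hard_vote"] == out["true_label"]
        out["soft_correct"] = out["soft_vote"] == out["true_label"]
    return out


def run_aggressiveness(
    matrix: pd.DataFrame,
    features: list[str],
    train_frac: float = 0.70,
    seed: int = 0,
    n_boot: int = 2000,
) -> EvaluationReport:
    """Re-run the evaluation within the PCa group: AG vs NAG.

    Uses the four-model set (no SVM), AG as the positive class, a stratified
    ``train_frac`` split of the PCa samples, and proPSA as the univariate
    baseline marker.
    """
    pca = matrix[matrix["aggressiveness"].isin(["AG", "NAG"])]
    if pca.empty:
        raise ValueError("no Gleason-labelled PCa samples in the matrix")
    train, test = train_test_split(
        pca,
        train_size=train_frac,
        stratify=pca["aggressiveness"],
        random_state=seed,
    )
    return train_and_score(
        train,
        test,
        features,
        label_col="aggressiveness",
        positive_label="AG",
        model_names=AGGRESSIVENESS_MODELS,
        seed=seed,
        n_boot=n_boot,
        baseline_col="propsa",
    )
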