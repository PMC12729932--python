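"""Fixed-hyperparameter classifiers and the cross-validation harness.

Three binary classifiers with a-priori hyperparameters are compared:

* SVC — RBF-kernel support vector classifier, C = 1.0, gamma = 'scale';
* EN  — elastic-net logistic regression, l1_ratio = 0.5, SAGA solver,
  max_iter = 10000;
* RF  — random forest, 100 trees, Gini criterion, unrestricted depth.

Each is evaluated by stratified shuffled 5-fold cross-validation.  Within
each fold, variants that were not hemisphere-normalized upstream are
Min-Max scaled with parameters fit on the training rows only; an optional
recursive-feature-elimination step (also training-rows-only) precedes the
fit.  Per fold the harness records accuracy/precision/recall/F1 from the
confusion matrix, ROC AUC from continuous scores, the selected features,
and mean-|Shapley| feature attributions on the test rows.  STN is the
positive class (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .outliers import DatasetVariant
from .shapley import shapley_values
from .synth import STN

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "ConfusionCounts",
    "CvResult",
    "make_model",
    "stratified_folds",
    "confusion_metrics",
    "rfe_select",
    "run_model",
]

MODEL_KINDS = ("SVC", "EN", "RF")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model configurations (3 kinds x RFE on/off)."""

    kind: str
    use_rfe: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")


def make_model(spec: ModelSpec):
    if spec.kind == "SVC":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=spec.seed)
    if spec.kind == "EN":
        # l1_ratio between 0 and 1 selects the elastic-net penalty
        return LogisticRegression(
            l1_ratio=0.5,
            solver="saga",
            max_iter=10_000,
            random_state=spec.seed,
        )
    return RandomForestClassifier(
        n_estimators=100,
        criterion="gini",
        max_depth=None,
        min_samples_split=2,
        min_samples_leaf=1,
        random_state=spec.seed,
        n_jobs=1,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from the confusion counts.

    Degenerate conventions: precision is 0 when no positive predictions
    exist, recall is 0 when no positives exist, and F1 is 0 when
    precision + recall is 0.
    """
    if c.total <= 0:
        raise ValueError("confusion matrix is empty")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def stratified_folds(
    labels: Sequence[int] | np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified k-fold assignment (deterministic in ``seed``)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= {k} members for {k}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _importance(spec: ModelSpec, model, X: np.ndarray, y: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Feature importances used for the elimination order."""
    if spec.kind == "EN":
        return np.abs(model.coef_[0])
    if spec.kind == "RF":
        return model.feature_importances_
    # RBF SVC exposes no coefficients: permutation importance on the
    # training rows (mean accuracy drop over 3 shuffles per feature)
    base = model.score(X, y)
    p = X.shape[1]
    imp = np.zeros(p)
    for j in range(p):
        drops = []
        for _ in range(3):
            Xs = X.copy()
            Xs[:, j] = rng.permutation(Xs[:, j])
            drops.append(base - model.score(Xs, y))
        imp[j] = np.mean(drops)
    return imp


def rfe_select(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    cv: int = 3,
    score_step: int = 1,
) -> np.ndarray:
    """Recursive feature elimination with internal cross-validation.

    Features are removed one at a time (least important first, by
    model-appropriate importance), producing nested subsets from all
    features down to one; each subset size is then scored by internal
    stratified ``cv``-fold accuracy and the best-scoring subset is
    returned (ties favor fewer features).  ``score_step`` > 1 scores only
    every that-many-th subset size (the full and single-feature subsets
    are always scored), trading resolution of the size search for speed.
    Uses only the rows passed in, so applying it to a training fold
    cannot leak test information.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    order = list(range(p))  # active feature indices
    subsets: list[list[int]] = [order.copy()]
    while len(order) > 1:
        model = make_model(spec).fit(X[:, order], y)
        imp = _importance(spec, model, X[:, order], y, rng)
        drop = order[int(np.argmin(imp))]
        order = [j for j in order if j != drop]
        subsets.append(order.copy())

    if score_step > 1:
        scored = subsets[::score_step]
        if subsets[-1] not in scored:
            scored.append(subsets[-1])
    else:
        scored = subsets
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(X, y)]
    best_score, best_subset = -np.inf, scored[0]
    for subset in scored:
        cols = np.asarray(subset)
        scores = []
        for tr, te in splits:
            m = make_model(spec).fit(X[np.ix_(tr, cols)], y[tr])
            scores.append(m.score(X[np.ix_(te, cols)], y[te]))
        score = float(np.mean(scores))
        # >= so later (smaller) subsets win ties
        if score >= best_score:
            best_score, best_subset = score, subset
    return np.asarray(sorted(best_subset))


@dataclass
class CvResult:
    """Per-fold outcome of one model on one dataset variant."""

    spec: ModelSpec
    fold_metrics: pd.DataFrame  # one row per fold: accuracy..auc
    selected_features: list[list[str]] = field(default_factory=list)
    shap_mean_abs: list[pd.Series] = field(default_factory=list)
    fold_assignments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    # per fold: (data_min_, data_max_) of the training-rows-only Min-Max
    # scaler, or None for pre-normalized variants
    fold_scalers: list[tuple[np.ndarray, np.ndarray] | None] = field(default_factory=list)

    @property
    def mean_metrics(self) -> pd.Series:
        return self.fold_metrics[["accuracy", "precision", "recall", "f1", "auc"]].mean()


def _scores(spec: ModelSpec, model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for ROC: decision values for SVC, class-1
    probability for EN/RF."""
    if spec.kind == "SVC":
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def run_model(
    variant: DatasetVariant,
    spec: ModelSpec,
    k: int = 5,
    compute_shap: bool = True,
    shap_max_points: int = 40,
    shap_permutations: int = 12,
    rfe_score_step: int = 1,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> CvResult:
    """Cross-validate one model configuration on one dataset variant."""
    table = variant.table
    X_all = table[list(feature_names)].to_numpy(float)
    y_all = (table["label"] == STN).to_numpy(int)
    folds = stratified_folds(y_all, k=k, seed=spec.seed)
    names = np.asarray(feature_names)

    rows = []
    selected: list[list[str]] = []
    shap_series: list[pd.Series] = []
    fold_scalers: list[tuple[np.ndarray, np.ndarray] | None] = []
    for fold_i, (tr, te) in enumerate(folds):
        X_tr, X_te = X_all[tr], X_all[te]
        y_tr, y_te = y_all[tr], y_all[te]
        if not variant.pre_normalized:
            scaler = MinMaxScaler().fit(X_tr)
            fold_scalers.append((scaler.data_min_.copy(), scaler.data_max_.copy()))
            X_tr = scaler.transform(X_tr)
            X_te = scaler.transform(X_te)
        else:
            fold_scalers.append(None)
        if spec.use_rfe:
            cols = rfe_select(
                spec, X_tr, y_tr, seed=spec.seed + fold_i,
                score_step=rfe_score_step,
            )
        else:
            cols = np.arange(X_tr.shape[1])
        X_tr, X_te = X_tr[:, cols], X_te[:, cols]
        model = make_model(spec).fit(X_tr, y_tr)
        pred = model.predict(X_te)
        counts = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (y_te == 1))),
            tn=int(np.sum((pred == 0) & (y_te == 0))),
            fp=int(np.sum((pred == 1) & (y_te == 0))),
            fn=int(np.sum((pred == 0) & (y_te == 1))),
        )
        metrics = confusion_metrics(counts)
        metrics["auc"] = float(roc_auc_score(y_te, _scores(spec, model, X_te)))
        metrics["fold"] = fold_i
        rows.append(metrics)
        selected.append([str(n) for n in names[cols]])
        if compute_shap:
            rng = np.random.default_rng(spec.seed * 1000 + fold_i)
            n_pts = min(shap_max_points, len(te))
            pts = (
                rng.choice(len(te), size=n_pts, replace=False)
                if n_pts < len(te)
                else np.arange(len(te))
            )
            phi = shapley_values(
                lambda Z: _scores(spec, model, Z),
                X_te[pts],
                reference=X_tr.mean(axis=0),
                n_permutations=shap_permutations,
                rng=rng,
            )
            shap_series.append(
                pd.Series(np.abs(phi).mean(axis=0), index=names[cols])
            )
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    return CvResult(
        spec=spec,
        fold_metrics=fold_metrics,
        selected_features=selected,
        shap_mean_abs=shap_series,
        fold_assignments=folds,
        fold_scalers=fold_scalers,
    )
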