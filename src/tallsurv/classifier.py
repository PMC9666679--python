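"""Supervised subgroup classifier and risk score.

Features are standardized with parameters fit on the training partition only
(Z = (X - U) / S with U the training mean and S the training standard
deviation), then a gradient-boosted decision-tree ensemble is tuned by
exhaustive grid search under stratified 5-fold cross-validated accuracy and
refit on the full training partition. The model's predicted probability of
membership in the poor-survival subgroup K1 is the per-sample survival risk
score.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100, 200],
}


@dataclass
class StandardizerParams:
    """Training-set center/scale. Zero-variance training features are
    recorded and standardize to exactly 0 in any cohort they are applied to."""

    center: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray  # boolean mask of dropped-scale features

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        safe_scale = np.where(self.zero_variance, 1.0, self.scale)
        Z = (X - self.center) / safe_scale
        Z[:, self.zero_variance] = 0.0
        return Z


@dataclass
class BoostedClassifier:
    model: XGBClassifier
    best_params: dict
    cv_table: list[dict]
    n_features: int
    seed: int


def fit_standardizer(X_train: np.ndarray) -> StandardizerParams:
    """Column mean/standard deviation (population convention) on training data."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("standardizer needs a 2-D matrix with at least 2 samples")
    center = X_train.mean(axis=0)
    scale = X_train.std(axis=0)  # population (ddof=0), the common standardizer convention
    zero_var = scale == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance feature(s) standardized to 0")
    return StandardizerParams(center=center, scale=scale, zero_variance=zero_var)


def _make_xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
        verbosity=0,
    )


def train_classifier(
    X_train: np.ndarray,
    labels: np.ndarray,
    grid: dict[str, list] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> BoostedClassifier:
    """Grid search over boosted-tree hyperparameters by stratified K-fold CV
    accuracy; the winner is refit on the whole training partition.

    Ties in CV accuracy break toward the earlier grid point (deterministic
    given seed, grid and data).
    """
    X_train = np.asarray(X_train, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if len(labels) < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} samples")
    grid = DEFAULT_GRID if grid is None else grid
    keys = list(grid)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X_train, labels))
    cv_table: list[dict] = []
    best_acc, best_params = -1.0, None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        accs = []
        for tr, va in folds:
            clf = _make_xgb(params, seed)
            clf.fit(X_train[tr], labels[tr])
            accs.append(float((clf.predict(X_train[va]) == labels[va]).mean()))
        mean_acc = float(np.mean(accs))
        cv_table.append({"params": params, "fold_accuracies": accs, "mean_accuracy": mean_acc})
        if mean_acc > best_acc:
            best_acc, best_params = mean_acc, params
    final = _make_xgb(best_params, seed)
    final.fit(X_train, labels)
    return BoostedClassifier(
        model=final, best_params=best_params, cv_table=cv_table, n_features=X_train.shape[1], seed=seed
    )


def predict_risk(
    model: BoostedClassifier, std: StandardizerParams, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted subgroup labels and K1-membership probability (risk score).

    The label is K1 exactly when the risk exceeds 0.5 (a tie at 0.5 resolves
    to K0).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    Z = std.apply(X)
    proba = model.model.predict_proba(Z)
    classes = list(model.model.classes_)
    if len(classes) == 2:
        risk = proba[:, classes.index(1)]
        labels = (risk > 0.5).astype(int)
    else:  # >2 subgroups: argmax labels, risk = membership in the last (worst) group
        risk = proba[:, classes.index(max(classes))]
        labels = np.asarray(classes)[proba.argmax(axis=1)]
    return labels, risk
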