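"""Per-endpoint sub-models: random forest, RBF support-vector classifier and
a one-hidden-layer feed-forward (error-backpropagation) network, each tuned
by exhaustive grid search scored with stratified five-fold CV accuracy.

Scores are positive-class probabilities in [0, 1] (vote fraction for the
forest, Platt-calibrated probability for the SVC, output-unit activation
for the network); decisions are scores thresholded at 0.5. Everything is
seeded, so a re-run with the same data, grid and seed reproduces the chosen
hyperparameters and every decision bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "ALGORITHMS", "DEFAULT_GRIDS", "SubModelSpec", "SubModelResult",
    "make_estimator", "grid_search_fit", "predict_scores", "cross_validate",
]

ALGORITHMS = ("RF", "SVM", "BP")

#: Default hyperparameter grids (the search spaces, not fixed choices).
DEFAULT_GRIDS = {
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    "SVM": {"C": [0.1, 1, 10, 100], "gamma": ["scale", 0.01, 0.1]},
    "BP": {"hidden_layer_sizes": [(32,), (64,), (128,)], "alpha": [1e-4, 1e-3]},
}


@dataclass
class SubModelSpec:
    algorithm: str
    grid: dict = None
    cv_folds: int = 5
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must lie in (0, 1)")


@dataclass
class SubModelResult:
    endpoint: str
    algorithm: str
    best_params: dict
    model: object
    cv_accuracy: float                  # CV accuracy of the chosen config
    train_accuracy: float               # resubstitution accuracy, labeled as such
    feature_names: list = field(default_factory=list)
    spec: SubModelSpec = None
    scores: dict = field(default_factory=dict)      # split -> np.ndarray
    decisions: dict = field(default_factory=dict)   # split -> np.ndarray

    def manifest(self) -> dict:
        import sklearn
        return {
            "endpoint": self.endpoint,
            "algorithm": self.algorithm,
            "best_params": {k: (str(v) if v is None or isinstance(v, tuple) else v)
                            for k, v in self.best_params.items()},
            "seed": self.spec.seed if self.spec else None,
            "cv_folds": self.spec.cv_folds if self.spec else None,
            "decision_threshold": self.spec.decision_threshold if self.spec else None,
            "cv_accuracy": self.cv_accuracy,
            "train_accuracy": self.train_accuracy,
            "n_features": len(self.feature_names),
            "sklearn_version": sklearn.__version__,
        }

    def save(self, directory) -> None:
        import joblib
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        stem = f"{self.algorithm}_{self.endpoint}"
        joblib.dump(self.model, d / f"{stem}.joblib")
        manifest = self.manifest()
        manifest["feature_names"] = list(self.feature_names)
        (d / f"{stem}.json").write_text(json.dumps(manifest, indent=2))


def make_estimator(algorithm: str, seed: int = 0):
    """Unfitted sklearn estimator for one algorithm family."""
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "SVM":
        # probability=True enables Platt-type score calibration
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algorithm == "BP":
        # sigmoid hidden units, cross-entropy loss; the raised learning rate
        # and patience keep adam from stalling at the majority class on
        # small binary panels
        return MLPClassifier(activation="logistic", solver="adam",
                             learning_rate_init=0.01, early_stopping=True,
                             n_iter_no_change=25, max_iter=500,
                             random_state=seed)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def _check_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y row counts differ")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: only one class present")
    return X, y


def grid_search_fit(X, y, spec: SubModelSpec, *, endpoint: str = "Y",
                    feature_names=None) -> SubModelResult:
    """Exhaustive grid search scored by stratified k-fold CV accuracy, then a
    refit of the best configuration on the whole training split."""
    X, y = _check_xy(X, y)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                         random_state=spec.seed)
    gs = GridSearchCV(make_estimator(spec.algorithm, spec.seed), spec.grid,
                      scoring="accuracy", cv=cv, n_jobs=1, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        gs.fit(X, y)

    model = gs.best_estimator_
    scores_train = predict_scores(model, X)
    decisions_train = (scores_train >= spec.decision_threshold).astype(int)
    return SubModelResult(
        endpoint=endpoint,
        algorithm=spec.algorithm,
        best_params=dict(gs.best_params_),
        model=model,
        cv_accuracy=float(gs.best_score_),
        train_accuracy=float((decisions_train == y).mean()),
        feature_names=list(feature_names) if feature_names is not None else [],
        spec=spec,
        scores={"train": scores_train},
        decisions={"train": decisions_train},
    )


def predict_scores(model, X) -> np.ndarray:
    """Positive-class score in [0, 1] for each row of X."""
    X = np.asarray(X, dtype=np.float64)
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(f"feature mismatch: model expects {n_expected} "
                         f"columns, got {X.shape[1]}")
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(1)
    return np.clip(proba[:, pos_col], 0.0, 1.0)


def apply_to_split(result: SubModelResult, X, split_name: str,
                   threshold: float | None = None) -> SubModelResult:
    """Score a data split and cache scores/decisions on the result."""
    thr = threshold if threshold is not None else result.spec.decision_threshold
    s = predict_scores(result.model, X)
    result.scores[split_name] = s
    result.decisions[split_name] = (s >= thr).astype(int)
    return result


def cross_validate(X, y, spec: SubModelSpec, estimator=None):
    """Stratified k-fold CV of one configuration.

    Returns ``(Q, fold_accuracies)`` where Q is the pooled out-of-fold
    accuracy. If some fold's training part is single-class the partition is
    re-drawn once with a shifted seed before giving up.
    """
    X, y = _check_xy(X, y)
    if estimator is None:
        estimator = make_estimator(spec.algorithm, spec.seed)

    for attempt, seed in enumerate((spec.seed, spec.seed + 1)):
        cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                             random_state=seed)
        folds = list(cv.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
        if attempt == 0:
            warnings.warn("single-class CV fold; re-drawing the partition once")
    else:
        raise ValueError("could not build CV folds with both classes present")

    from sklearn.base import clone
    oof = np.empty(len(y), dtype=int)
    fold_acc = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in folds:
            m = clone(estimator).fit(X[tr], y[tr])
            pred = (predict_scores(m, X[te]) >= spec.decision_threshold).astype(int)
            oof[te] = pred
            fold_acc.append(float((pred == y[te]).mean()))
    return float((oof == y).mean()), fold_acc
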