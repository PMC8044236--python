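"""Cross-endpoint fingerprint selection by SHAP-quintile intersection.

For each endpoint (Y1, Y2, Y3) a backing classifier is fitted on the
training split and every fingerprint bit receives a global importance: the
mean absolute SHAP value of that bit over the training compounds. Bits are
ranked per endpoint, the top fraction (a quintile by default, floor(881/5)
= 176 bits) is taken from each ranking, and the final descriptor set is the
intersection of the three top sets — bits that matter for *all three*
evidence groups. The selected set is ordered by the mean of the three
importances, descending.

Selection sees only the training split, so no test information leaks into
the descriptor choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .dataset import ModelingDataset
from .treeshap import forest_shap_values

__all__ = [
    "FeatureRanking", "FeatureSelectionResult", "DEFAULT_BACKING_MODEL",
    "shap_importance", "top_fraction", "intersect_rankings", "select_features",
]

#: Backing model for attribution: a bounded-depth random forest. Depth is
#: capped so tree-path attribution stays cheap and the fit regularized.
DEFAULT_BACKING_MODEL = {"n_estimators": 200, "max_depth": 8}


@dataclass
class FeatureRanking:
    """Global importance ranking of all fingerprint bits for one endpoint."""
    endpoint: str
    importance: np.ndarray        # mean |SHAP| per feature, >= 0
    signed_mean: np.ndarray       # mean signed SHAP, kept for inspection
    order: np.ndarray             # feature indices, descending importance

    def __post_init__(self):
        imp = np.asarray(self.importance, dtype=float)
        if not np.all(np.isfinite(imp)) or (imp < 0).any():
            raise ValueError("importances must be finite and non-negative")
        if sorted(self.order) != list(range(len(imp))):
            raise ValueError("order must be a permutation of the feature indices")

    def to_frame(self, feature_names=None) -> pd.DataFrame:
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(len(self.importance))])
        return pd.DataFrame({
            "feature": [names[i] for i in self.order],
            "feature_index": self.order,
            "importance": self.importance[self.order],
            "rank": np.arange(1, len(self.order) + 1),
        })


@dataclass
class FeatureSelectionResult:
    rankings: dict                      # endpoint -> FeatureRanking
    quintile_fraction: float
    top_sets: dict                      # endpoint -> frozenset of indices
    selected: list = field(default_factory=list)  # indices, descending mean importance

    def selected_names(self, feature_names) -> list:
        return [feature_names[i] for i in self.selected]


def _rank(importance: np.ndarray) -> np.ndarray:
    # descending importance, ties broken by ascending feature index
    return np.lexsort((np.arange(len(importance)), -importance))


def shap_importance(X_train, y, endpoint: str = "Y", model=None,
                    seed: int = 0) -> FeatureRanking:
    """Fit the backing classifier and aggregate per-feature attributions.

    Importance of a feature is the mean absolute SHAP value over the
    training compounds; a constant column gets exactly zero. ``model`` may
    be an unfitted sklearn forest; by default a bounded-depth random forest
    seeded with ``seed`` is used.
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"degenerate labels for {endpoint}: single class")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 training compounds for attribution")

    if model is None:
        model = RandomForestClassifier(random_state=seed, n_jobs=1,
                                       **DEFAULT_BACKING_MODEL)
    model.fit(X, y)
    phi, _ = forest_shap_values(model, X)
    importance = np.abs(phi).mean(axis=0)
    return FeatureRanking(endpoint=endpoint, importance=importance,
                          signed_mean=phi.mean(axis=0), order=_rank(importance))


def top_fraction(ranking: FeatureRanking, fraction: float = 0.2) -> frozenset:
    """First ``floor(n_features * fraction)`` indices of the ranking."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.floor(len(ranking.order) * fraction))
    return frozenset(int(i) for i in ranking.order[:k])


def intersect_rankings(top_sets: dict, rankings: dict,
                       quintile_fraction: float = 0.2) -> FeatureSelectionResult:
    """Intersect the per-endpoint top sets; order the survivors by
    descending mean importance across the three rankings."""
    selected_set = None
    for s in top_sets.values():
        selected_set = set(s) if selected_set is None else selected_set & set(s)
    selected_set = selected_set or set()
    if not selected_set:
        warnings.warn("empty cross-endpoint intersection; no features selected",
                      stacklevel=2)
    mean_imp = np.mean([r.importance for r in rankings.values()], axis=0)
    selected = sorted(selected_set, key=lambda i: (-mean_imp[i], i))
    return FeatureSelectionResult(rankings=dict(rankings),
                                  quintile_fraction=quintile_fraction,
                                  top_sets=dict(top_sets), selected=selected)


def select_features(ds: ModelingDataset, fraction: float = 0.2,
                    seed: int = 0, model_factory=None) -> FeatureSelectionResult:
    """Run per-endpoint attribution on the training split and intersect the
    top-``fraction`` sets. ``model_factory(endpoint, seed)`` may supply a
    custom backing classifier per endpoint."""
    X_train, Y_train = ds.subset("train")
    rankings, tops = {}, {}
    for ep in Y_train.columns:
        model = model_factory(ep, seed) if model_factory is not None else None
        r = shap_importance(X_train.to_numpy(), Y_train[ep].to_numpy(),
                            endpoint=ep, model=model, seed=seed)
        rankings[ep] = r
        tops[ep] = top_fraction(r, fraction)
    return intersect_rankings(tops, rankings, quintile_fraction=fraction)


def save_selection(result: FeatureSelectionResult, directory, feature_names) -> None:
    """Persist rankings (CSV per endpoint) and the selected-feature list
    (one fingerprint name per line)."""
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for ep, r in result.rankings.items():
        r.to_frame(feature_names).to_csv(d / f"ranking_{ep}.csv", index=False)
    (d / "selected_features.txt").write_text(
        "\n".join(result.selected_names(list(feature_names))) + "\n")


def plot_top_features(result: FeatureSelectionResult, feature_names,
                      directory, k: int = 20) -> list:
    """Bar plot of the top-k bits per endpoint (global mean |SHAP|)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for ep, r in result.rankings.items():
        idx = r.order[:k]
        fig, ax = plt.subplots(figsize=(6, 0.3 * k + 1))
        ax.barh([feature_names[i] for i in idx][::-1],
                r.importance[idx][::-1], color="steelblue")
        ax.set_xlabel("mean |SHAP|")
        ax.set_title(f"Top {k} fingerprints for {ep}")
        fig.tight_layout()
        p = d / f"top_features_{ep}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
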