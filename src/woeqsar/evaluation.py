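"""Classification metrics and report layouts for the QSAR pipeline.

Implements the standard confusion-matrix rates — accuracy Q = (TP+TN)/n,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2pr/(p+r) — reported for
both the positive and the negative class (the negative block treats 0 as
the class of interest), plus rank-based ROC/AUC. A metric whose denominator
is zero is *undefined* and reported as NaN, never coerced to 0 or 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion", "accuracy", "precision",
    "recall", "f1", "per_class_metrics", "roc_auc", "round_half_up",
    "render_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the negative class treated as the class of interest."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def _as_binary(v, name):
    a = np.asarray(v).astype(int).ravel()
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return a


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.n if c.n else math.nan


def precision(c: ConfusionCounts) -> float:
    d = c.tp + c.fp
    return c.tp / d if d else math.nan


def recall(c: ConfusionCounts) -> float:
    d = c.tp + c.fn
    return c.tp / d if d else math.nan


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall, 2pr/(p+r)."""
    if math.isnan(p) or math.isnan(r) or (p + r) == 0:
        return math.nan
    return 2 * p * r / (p + r)


def per_class_metrics(y_true, y_pred) -> dict:
    """Precision/recall/F1 for the positive and the negative class plus the
    shared accuracy, keyed like ``precision_pos`` / ``recall_neg`` ..."""
    c = confusion(y_true, y_pred)
    cneg = c.swapped()
    p_pos, r_pos = precision(c), recall(c)
    p_neg, r_neg = precision(cneg), recall(cneg)
    return {
        "accuracy": accuracy(c),
        "precision_pos": p_pos, "recall_pos": r_pos, "f1_pos": f1(p_pos, r_pos),
        "precision_neg": p_neg, "recall_neg": r_neg, "f1_neg": f1(p_neg, r_neg),
        "confusion": c,
    }


def roc_auc(y_true, scores):
    """AUC (rank statistic with midrank tie handling) and the ROC curve.

    Returns ``(auc, points)`` where points is an array of (fpr, tpr) rows;
    a single-class truth vector yields (NaN, empty)."""
    t = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float).ravel()
    if len(t) != len(s):
        raise ValueError("length mismatch between labels and scores")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(t)) < 2:
        return math.nan, np.empty((0, 2))
    fpr, tpr, _ = roc_curve(t, s)
    return float(roc_auc_score(t, s)), np.column_stack([fpr, tpr])


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up used for printed tables (0.5 ulp goes up)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = 10 ** ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


@dataclass
class MetricsReport:
    """Full metric block for one (algorithm, endpoint-or-fusion, split)."""
    algorithm: str
    target: str        # "Y1"/"Y2"/"Y3" or "fusion"
    split: str         # "train"/"test"/"cv"
    metrics: dict = field(default_factory=dict)
    auc: float = math.nan
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    cv_fold_accuracies: list = field(default_factory=list)

    def row(self) -> dict:
        c = self.metrics.get("confusion")
        out = {"algorithm": self.algorithm, "target": self.target,
               "split": self.split}
        for k, v in self.metrics.items():
            if k == "confusion":
                out.update(TP=c.tp, TN=c.tn, FP=c.fp, FN=c.fn)
            else:
                out[k] = round_half_up(v, 3)
        out["auc"] = round_half_up(self.auc, 3) if not math.isnan(self.auc) else math.nan
        return out

    def to_json(self) -> str:
        d = self.row()
        return json.dumps({k: (None if isinstance(v, float) and math.isnan(v) else v)
                           for k, v in d.items()}, indent=2, sort_keys=True)


def evaluate_predictions(y_true, y_pred, scores=None, *, algorithm="",
                         target="", split="") -> MetricsReport:
    """Bundle per-class metrics (and AUC when scores are given)."""
    rep = MetricsReport(algorithm=algorithm, target=target, split=split,
                        metrics=per_class_metrics(y_true, y_pred))
    if scores is not None:
        rep.auc, rep.roc_points = roc_auc(y_true, scores)
    return rep


def render_reports(reports, directory=None, plot_roc=True):
    """Render a list of :class:`MetricsReport` into the three table layouts:

    * ``accuracy_table`` — accuracy per (algorithm, target, split), wide;
    * ``submodel_table`` — per-class recall/precision/F1 + accuracy + AUC
      for the nine endpoint sub-models (test split);
    * ``fusion_table`` — the same block for the fused models.

    When ``directory`` is given, writes CSV/JSON (and ROC plots)."""
    rows = [r.row() for r in reports]
    flat = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["algorithm", "target", "split"])

    if len(flat):
        acc = flat.pivot_table(index="algorithm", columns=["target", "split"],
                               values="accuracy", aggfunc="first", sort=False)
        sub = flat[(flat["target"] != "fusion") & (flat["split"] == "test")]
        fus = flat[flat["target"] == "fusion"]
    else:
        acc = pd.DataFrame()
        sub = flat.copy()
        fus = flat.copy()

    tables = {"accuracy_table": acc, "submodel_table": sub, "fusion_table": fus,
              "all_rows": flat}

    if directory is not None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, tb in tables.items():
            tb.to_csv(d / f"{name}.csv")
        (d / "metrics.json").write_text(json.dumps(
            {"schema_version": 1,
             "rows": json.loads(flat.to_json(orient="records"))}, indent=2))
        if plot_roc:
            _plot_rocs(reports, d)
    return tables


def _plot_rocs(reports, directory):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with_curves = [r for r in reports if len(r.roc_points)]
    if not with_curves:
        return
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in with_curves:
        ax.plot(r.roc_points[:, 0], r.roc_points[:, 1],
                label=f"{r.algorithm}/{r.target} ({r.split}) AUC={r.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(directory / "roc_curves.png", dpi=120)
    plt.close(fig)
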