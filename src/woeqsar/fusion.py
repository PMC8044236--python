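"""Weight-of-evidence fusion of the three endpoint sub-models.

The fusion rule is the evidence rule itself: a compound is judged positive
when *any* of the three sub-models under one algorithm calls it positive,
and negative only when all three are negative — a logical OR over the
sub-decisions. For threshold-free ROC analysis the three sub-model scores
are combined by the noisy-OR, ``1 - (1-s1)(1-s2)(1-s3)``, the probability
of at least one positive under independence; it is the score-level analogue
of the OR rule (thresholding the fused score at ``1-(1-t)^3`` equals OR-ing
the sub-decisions thresholded at ``t``).

The reference label a fused prediction is judged against is the OR of the
three *observed* endpoint labels — overall mutagenicity under the
weight-of-evidence reading of the assays themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, evaluate_predictions

__all__ = [
    "fuse_decisions", "fuse_scores", "derive_reference_label",
    "fuse_submodels", "evaluate_fusion", "FusionResult",
]


def fuse_decisions(d1, d2, d3):
    """All-negative -> negative, otherwise positive (logical OR).

    Accepts scalars or aligned arrays of 0/1."""
    a = np.asarray(d1), np.asarray(d2), np.asarray(d3)
    for x in a:
        if not np.isin(x, (0, 1)).all():
            raise ValueError("sub-decisions must be 0/1")
    out = (a[0] | a[1] | a[2]).astype(int)
    return int(out) if out.ndim == 0 else out


def fuse_scores(s1, s2, s3):
    """Noisy-OR combination ``1 - (1-s1)(1-s2)(1-s3)`` of [0,1] scores."""
    a = [np.asarray(s, dtype=float) for s in (s1, s2, s3)]
    for x in a:
        if (x < 0).any() or (x > 1).any():
            raise ValueError("scores must lie in [0, 1]")
    out = 1.0 - (1.0 - a[0]) * (1.0 - a[1]) * (1.0 - a[2])
    return float(out) if out.ndim == 0 else out


def derive_reference_label(y1, y2, y3):
    """Overall mutagenicity: OR of the observed endpoint labels."""
    return fuse_decisions(y1, y2, y3)


@dataclass
class FusionResult:
    """Per-compound fusion table plus provenance for one algorithm."""
    algorithm: str
    table: pd.DataFrame  # d1..d3, s1..s3, fused_decision, fused_score, reference_label

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def fuse_submodels(sub_results, Y, split: str = "test",
                   compound_ids=None) -> FusionResult:
    """Combine three fitted sub-model results (one per endpoint, same
    algorithm) into the per-compound fusion table for one split.

    ``sub_results`` maps endpoint -> SubModelResult; ``Y`` is the observed
    label DataFrame (columns Y1..Y3) for the same compounds, in the same
    row order as the cached scores.
    """
    eps = ("Y1", "Y2", "Y3")
    if set(sub_results) != set(eps):
        raise ValueError(f"need exactly the sub-models {eps}")
    algos = {r.algorithm for r in sub_results.values()}
    if len(algos) != 1:
        raise ValueError(f"sub-models mix algorithms: {sorted(algos)}")
    lengths = {len(sub_results[ep].scores[split]) for ep in eps}
    if len(lengths) != 1 or lengths != {len(Y)}:
        raise ValueError("sub-model predictions and labels are not aligned")

    s = {ep: np.asarray(sub_results[ep].scores[split]) for ep in eps}
    d = {ep: np.asarray(sub_results[ep].decisions[split]) for ep in eps}
    table = pd.DataFrame({
        "d1": d["Y1"], "d2": d["Y2"], "d3": d["Y3"],
        "s1": s["Y1"], "s2": s["Y2"], "s3": s["Y3"],
        "fused_decision": fuse_decisions(d["Y1"], d["Y2"], d["Y3"]),
        "fused_score": fuse_scores(s["Y1"], s["Y2"], s["Y3"]),
        "reference_label": derive_reference_label(
            Y["Y1"].to_numpy(), Y["Y2"].to_numpy(), Y["Y3"].to_numpy()),
    }, index=(compound_ids if compound_ids is not None else Y.index))
    return FusionResult(algorithm=algos.pop(), table=table)


def evaluate_fusion(fusion: FusionResult, split: str = "test") -> MetricsReport:
    """Full metric block of the fused verdict against the OR reference."""
    t = fusion.table
    return evaluate_predictions(
        t["reference_label"], t["fused_decision"], t["fused_score"],
        algorithm=fusion.algorithm, target="fusion", split=split)


def meta_fusion_model(sub_scores: np.ndarray, reference: np.ndarray, seed: int = 0):
    """Optional alternative: a logistic meta-classifier over the three
    sub-model scores instead of the deterministic OR rule (off by default in
    the pipeline)."""
    from sklearn.linear_model import LogisticRegression
    X = np.asarray(sub_scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("sub_scores must be n x 3")
    return LogisticRegression(random_state=seed).fit(X, np.asarray(reference).astype(int))
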