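"""End-to-end orchestration: assay integration -> dataset -> SHAP-quintile
feature selection -> per-endpoint sub-models -> weight-of-evidence fusion ->
metric reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import assays, dataset, fusion, models, selection
from .evaluation import MetricsReport, evaluate_predictions, render_reports

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    report: assays.IntegrationReport
    ds: dataset.ModelingDataset
    selection: selection.FeatureSelectionResult
    submodels: dict = field(default_factory=dict)   # (algo, endpoint) -> SubModelResult
    fusions: dict = field(default_factory=dict)     # algo -> FusionResult
    metrics: list = field(default_factory=list)     # MetricsReport rows

    def tables(self, directory=None):
        return render_reports(self.metrics, directory)

    def predictions_frame(self) -> pd.DataFrame:
        rows = []
        for (algo, ep), r in self.submodels.items():
            for split in r.scores:
                idx = self.ds.X.index[self.ds.split == split]
                for cid, s, d in zip(idx, r.scores[split], r.decisions[split]):
                    rows.append((cid, ep, algo, float(s), int(d), split))
        return pd.DataFrame(rows, columns=["compound_id", "endpoint",
                                           "algorithm", "score", "decision",
                                           "split"])


def run_pipeline(records, fingerprints, *, ratio: float = 0.8, seed: int = 0,
                 fraction: float = 0.2, algorithms=("RF", "SVM", "BP"),
                 grids=None, cv_folds: int = 5,
                 stratify: bool = False) -> PipelineResult:
    """Run the whole analysis on raw inputs.

    Parameters
    ----------
    records : iterable of AssayRecord (or a path to a long-format assay CSV)
    fingerprints : FingerprintMatrix (or a path to a PaDEL-dialect CSV)
    ratio, seed : train/test split fraction and RNG seed (also seeds folds,
        backing attribution and every stochastic fit)
    fraction : top-fraction per endpoint ranking before intersection
    algorithms : algorithm families to train ("RF", "SVM", "BP")
    grids : optional {algorithm: grid} overriding the defaults
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        records = assays.read_assay_table(records)
    if isinstance(fingerprints, (str, bytes)) or hasattr(fingerprints, "__fspath__"):
        fingerprints = dataset.read_fingerprint_table(fingerprints)

    labels, report = assays.build_label_table(records)
    ds = dataset.join_features_labels(fingerprints, labels)
    ds = dataset.split_train_test(ds, ratio=ratio, seed=seed, stratify=stratify)

    sel = selection.select_features(ds, fraction=fraction, seed=seed)
    cols = [ds.X.columns[i] for i in sel.selected]

    X_train, Y_train = ds.subset("train")
    X_test, Y_test = ds.subset("test")
    Xtr, Xte = X_train[cols].to_numpy(), X_test[cols].to_numpy()

    result = PipelineResult(report=report, ds=ds, selection=sel)
    for algo in algorithms:
        subs = {}
        for ep in ("Y1", "Y2", "Y3"):
            spec = models.SubModelSpec(
                algorithm=algo, seed=seed, cv_folds=cv_folds,
                grid=(grids or {}).get(algo))
            r = models.grid_search_fit(Xtr, Y_train[ep].to_numpy(), spec,
                                       endpoint=ep, feature_names=cols)
            models.apply_to_split(r, Xte, "test")
            subs[ep] = r
            result.submodels[(algo, ep)] = r
            result.metrics.append(evaluate_predictions(
                Y_test[ep], r.decisions["test"], r.scores["test"],
                algorithm=algo, target=ep, split="test"))
            result.metrics.append(evaluate_predictions(
                Y_train[ep], r.decisions["train"], r.scores["train"],
                algorithm=algo, target=ep, split="train"))

        fus = fusion.fuse_submodels(subs, Y_test, split="test")
        result.fusions[algo] = fus
        result.metrics.append(fusion.evaluate_fusion(fus, split="test"))
    return result
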