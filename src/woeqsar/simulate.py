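"""Synthetic compound panels with the statistical structure the pipeline
assumes, plus the ground truth needed for recovery tests.

Each compound gets 881 independent Bernoulli fingerprint bits with
per-feature prevalence drawn from a configurable range. Three correlated
binary endpoint labels (Y1, Y2, Y3) are drawn from logistic models whose
active sets share a common core ``C`` (bits informative for *all three*
endpoints — exactly what the quintile-intersection selector is built to
find) plus per-endpoint private sets. Intercepts are calibrated on the
realized bit matrix so the endpoint positive rates hit configurable targets
(defaults echo a real-world mutagenicity panel: roughly 43/56/53% for
Y1/Y2/Y3). Labels are then flipped with a small noise rate, and 1-3
redundant assay records per endpoint are emitted with their own flip noise,
which exercises the singleton, majority and tie paths of outcome voting.
A configurable fraction of compounds loses all records of one group
(missingness) and individual records may be inconclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .assays import AssayRecord, POSITIVE, NEGATIVE, INCONCLUSIVE
from .dataset import FingerprintMatrix, N_PUBCHEM_BITS

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_panel", "panel_to_files"]

_Y2_CODES = ("MN_VIVO", "BM_CA")
_Y3_CODES = ("VITRO_CA", "TK", "SPERM_CA", "DOM_LETHAL", "HGPRT", "UDS", "SLRL")


@dataclass
class SyntheticConfig:
    n_compounds: int = 2000
    n_features: int = N_PUBCHEM_BITS
    prevalence_range: tuple = (0.05, 0.5)
    core_size: int = 20              # bits informative for all three endpoints
    private_size: int = 15           # extra bits per endpoint
    beta: float = 2.0                # log-odds effect per informative bit
    target_rates: tuple = (0.4323, 0.5564, 0.5301)   # P(Y_k = 1)
    label_flip: float = 0.05         # endpoint label noise
    records_range: tuple = (1, 3)    # assay records per endpoint per compound
    assay_flip: float = 0.10         # per-record flip noise
    inconclusive_rate: float = 0.02  # per-record chance of an inconclusive call
    missing_rate: float = 0.10       # chance a compound loses one whole group
    seed: int = 0

    def __post_init__(self):
        if self.core_size + 3 * self.private_size > self.n_features:
            raise ValueError("informative sets do not fit in the feature space")
        for r in self.target_rates:
            if not 0 < r < 1:
                raise ValueError(f"infeasible target positive rate: {r}")
        for p in (self.label_flip, self.assay_flip, self.inconclusive_rate,
                  self.missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.records_range
        if not 1 <= lo <= hi:
            raise ValueError("records_range must be 1 <= lo <= hi")


@dataclass
class SyntheticTruth:
    """Everything the generator knows; reproducible from config + seed."""
    config: SyntheticConfig
    core: list                       # shared informative bit indices
    private: dict                    # endpoint -> private bit indices
    informative: dict                # endpoint -> core + private
    intercepts: dict                 # endpoint -> calibrated intercept
    labels_prenoise: dict            # endpoint -> 0/1 array (pre flip-noise)
    labels: dict                     # endpoint -> 0/1 array (post flip-noise)
    missing_group: dict              # compound_id -> dropped group (if any)

    def to_json(self, path=None) -> str:
        d = {
            "config": asdict(self.config),
            "core": self.core,
            "private": self.private,
            "informative": self.informative,
            "intercepts": self.intercepts,
            "labels_prenoise": {k: np.asarray(v).tolist()
                                for k, v in self.labels_prenoise.items()},
            "labels": {k: np.asarray(v).tolist() for k, v in self.labels.items()},
            "missing_group": self.missing_group,
        }
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _calibrate_intercept(signal: np.ndarray, target: float) -> float:
    """Intercept a such that mean(sigmoid(a + signal)) == target."""
    f = lambda a: expit(a + signal).mean() - target
    return float(brentq(f, -50.0, 50.0, xtol=1e-10))


def generate_panel(config: SyntheticConfig):
    """Draw one panel. Returns ``(FingerprintMatrix, records, SyntheticTruth)``
    with records sorted by compound id; byte-identical for equal config."""
    rng = np.random.default_rng(config.seed)
    n, d = config.n_compounds, config.n_features
    width = max(4, len(str(n - 1)))
    ids = [f"C{i:0{width}d}" for i in range(n)]

    prevalence = rng.uniform(*config.prevalence_range, size=d)
    X = (rng.random((n, d)) < prevalence).astype(np.uint8)

    pool = rng.permutation(d)
    core = sorted(int(i) for i in pool[:config.core_size])
    private = {}
    off = config.core_size
    for ep in ("Y1", "Y2", "Y3"):
        private[ep] = sorted(int(i) for i in pool[off:off + config.private_size])
        off += config.private_size

    intercepts, labels_pre, labels = {}, {}, {}
    for k, ep in enumerate(("Y1", "Y2", "Y3")):
        active = core + private[ep]
        signal = config.beta * X[:, active].sum(axis=1).astype(float)
        a = _calibrate_intercept(signal, config.target_rates[k])
        y = (rng.random(n) < expit(a + signal)).astype(int)
        flips = rng.random(n) < config.label_flip
        intercepts[ep] = a
        labels_pre[ep] = y
        labels[ep] = np.where(flips, 1 - y, y)

    records: list[AssayRecord] = []
    missing: dict[str, str] = {}
    lo, hi = config.records_range
    groups = ("Y1", "Y2", "Y3")
    for i, cid in enumerate(ids):
        drop = None
        if rng.random() < config.missing_rate:
            drop = groups[rng.integers(3)]
            missing[cid] = drop
        for ep in groups:
            n_rec = int(rng.integers(lo, hi + 1))
            if ep == "Y1":
                codes = ["AMES"] * n_rec
            elif ep == "Y2":
                codes = [_Y2_CODES[rng.integers(2)] for _ in range(n_rec)]
            else:
                codes = [_Y3_CODES[rng.integers(len(_Y3_CODES))] for _ in range(n_rec)]
            if ep == drop:
                continue
            for code in codes:
                if rng.random() < config.inconclusive_rate:
                    records.append(AssayRecord(cid, code, INCONCLUSIVE))
                    continue
                obs = labels[ep][i]
                if rng.random() < config.assay_flip:
                    obs = 1 - obs
                records.append(AssayRecord(
                    cid, code, POSITIVE if obs else NEGATIVE))

    fp = FingerprintMatrix(ids, X)
    informative = {ep: sorted(core + private[ep]) for ep in groups}
    truth = SyntheticTruth(config=config, core=core, private=private,
                           informative=informative, intercepts=intercepts,
                           labels_prenoise=labels_pre, labels=labels,
                           missing_group=missing)
    return fp, records, truth


def panel_to_files(panel, directory) -> dict:
    """Write a generated panel to the module input formats: a PaDEL-dialect
    fingerprint CSV, a long-format assay CSV and a truth JSON. Returns the
    paths; reading the files back reproduces the in-memory panel."""
    from .dataset import write_fingerprint_table

    fp, records, truth = panel
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "fingerprints": d / "fingerprints.csv",
        "assays": d / "assays.csv",
        "truth": d / "truth.json",
    }
    write_fingerprint_table(fp, paths["fingerprints"])
    with open(paths["assays"], "w") as fh:
        fh.write("compound_id,assay_code,outcome\n")
        for r in records:
            fh.write(f"{r.compound_id},{r.assay_code},{r.outcome}\n")
    truth.to_json(paths["truth"])
    return paths
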