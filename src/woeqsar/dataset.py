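"""Fingerprint ingestion, feature/label joining and train/test splitting.

The fingerprint input is the PaDEL-Descriptor CSV dialect: a ``Name``
column followed by the 881 binary PubChem substructure keys
``PubchemFP0`` ... ``PubchemFP880``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_PUBCHEM_BITS = 881
FEATURE_NAMES = tuple(f"PubchemFP{i}" for i in range(N_PUBCHEM_BITS))

__all__ = [
    "N_PUBCHEM_BITS", "FEATURE_NAMES", "FingerprintMatrix", "ModelingDataset",
    "read_fingerprint_table", "write_fingerprint_table",
    "join_features_labels", "split_train_test",
]


@dataclass
class FingerprintMatrix:
    """n x 881 binary PubChem substructure key matrix."""
    compound_ids: list
    values: np.ndarray  # uint8, entries in {0,1}
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got shape {self.values.shape}")
        if len(self.compound_ids) != self.values.shape[0]:
            raise ValueError("compound_ids length does not match matrix rows")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            dupes = pd.Series(self.compound_ids).value_counts()
            raise ValueError(
                f"duplicate compound ids: {list(dupes[dupes > 1].index)[:5]}")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary fingerprint value at row {r} "
                f"({self.compound_ids[r]}), column {self.feature_names[c]}")
        self.values = self.values.astype(np.uint8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.compound_ids, name="Name"),
                            columns=list(self.feature_names))

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]


@dataclass
class ModelingDataset:
    """Aligned fingerprints + endpoint labels, with an optional split."""
    X: pd.DataFrame                      # n x 881, indexed by compound_id
    Y: pd.DataFrame                      # n x 3, columns Y1/Y2/Y3
    split: pd.Series | None = None       # 'train' / 'test' per compound
    split_seed: int | None = None
    split_ratio: float | None = None
    join_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.X.index.equals(self.Y.index):
            raise ValueError("fingerprint and label rows are not aligned")

    def subset(self, which: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        mask = self.split == which
        return self.X.loc[mask], self.Y.loc[mask]

    @property
    def n(self) -> int:
        return len(self.X)

    def manifest(self) -> dict:
        out = {"n": self.n, "split_ratio": self.split_ratio,
               "split_seed": self.split_seed, **self.join_info}
        if self.split is not None:
            out["n_train"] = int((self.split == "train").sum())
            out["n_test"] = int((self.split == "test").sum())
        return out

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.X.join(self.Y).to_csv(d / "dataset.csv")
        if self.split is not None:
            self.split.rename("split").to_csv(d / "split.csv")
        (d / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def read_fingerprint_table(path) -> FingerprintMatrix:
    """Read a PaDEL-dialect fingerprint CSV.

    The first column carries the compound name/ID; the remaining columns
    must be exactly PubchemFP0...PubchemFP880 (in order). Raises on the
    wrong column count or any non-binary cell, naming the offending place.
    """
    df = pd.read_csv(path)
    if df.shape[1] != N_PUBCHEM_BITS + 1:
        raise ValueError(
            f"expected 1 name column + {N_PUBCHEM_BITS} fingerprint columns, "
            f"found {df.shape[1]} columns in {path}")
    cols = list(df.columns[1:])
    if cols != list(FEATURE_NAMES):
        diff = [c for c, e in zip(cols, FEATURE_NAMES) if c != e][:3]
        raise ValueError(f"unexpected fingerprint columns (first mismatches: {diff})")
    ids = df.iloc[:, 0].astype(str).tolist()
    return FingerprintMatrix(ids, df.iloc[:, 1:].to_numpy())


def write_fingerprint_table(fp: FingerprintMatrix, path) -> None:
    fp.to_frame().to_csv(path)


def join_features_labels(fp: FingerprintMatrix, labels) -> ModelingDataset:
    """Inner-join fingerprints with endpoint labels on compound_id.

    ``labels`` is a list of ``EndpointLabelSet`` or an equivalent DataFrame.
    Rows are sorted by compound_id; counts dropped from each side are kept
    in ``join_info``.
    """
    from .assays import labels_to_frame

    ydf = labels if isinstance(labels, pd.DataFrame) else labels_to_frame(labels)
    xdf = fp.to_frame()
    xdf.index = xdf.index.astype(str)
    ydf.index = ydf.index.astype(str)
    shared = xdf.index.intersection(ydf.index).sort_values()
    if len(shared) == 0:
        raise ValueError("no compound ids shared between fingerprints and labels")
    info = {
        "n_joined": int(len(shared)),
        "n_fingerprint_only": int(len(xdf.index.difference(ydf.index))),
        "n_label_only": int(len(ydf.index.difference(xdf.index))),
    }
    return ModelingDataset(X=xdf.loc[shared], Y=ydf.loc[shared], join_info=info)


def split_train_test(ds: ModelingDataset, ratio: float = 0.8, seed: int = 0,
                     stratify: bool = False) -> ModelingDataset:
    """Assign each compound to train or test by uniform random draw.

    ``train size = round(n * ratio)`` (half-up), deterministic given
    ``seed``. With ``stratify=True`` the draw is done within each
    (Y1, Y2, Y3) label triple instead (off by default).
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = ds.n
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    rng = np.random.default_rng(seed)
    assignment = pd.Series("test", index=ds.X.index, name="split")

    if stratify:
        for _, grp in ds.Y.groupby(["Y1", "Y2", "Y3"]):
            k = int(np.floor(len(grp) * ratio + 0.5))
            pick = rng.permutation(len(grp))[:k]
            assignment.loc[grp.index[pick]] = "train"
    else:
        k = int(np.floor(n * ratio + 0.5))
        pick = rng.permutation(n)[:k]
        assignment.iloc[pick] = "train"

    return ModelingDataset(X=ds.X, Y=ds.Y, split=assignment,
                           split_seed=seed, split_ratio=ratio,
                           join_info=dict(ds.join_info))
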