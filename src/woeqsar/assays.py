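"""Integration of heterogeneous mutagenicity assay records into the three
ICH weight-of-evidence endpoint groups.

The standard genotoxicity batteries place each assay in one of three slots:

* **Y1** — the bacterial reverse mutation (Ames) test;
* **Y2** — in vivo mammalian cytogenetics: erythrocyte micronucleus or bone
  marrow chromosome aberration;
* **Y3** — the third, substitutable slot: in vitro mammalian chromosome
  aberration or TK gene mutation (battery option 1), germ-cell assays
  (spermatocyte chromosome aberration, rodent dominant lethal; option 2),
  plus the accepted supplements (HGPRT, unscheduled DNA synthesis,
  Drosophila sex-linked recessive lethal).

Within a group, multiple dichotomous outcomes are reconciled by majority
vote with ties resolved *positive* — the sensitivity-preserving convention.
A compound enters the modelling table only when all three groups have at
least one conclusive record.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "POSITIVE", "NEGATIVE", "INCONCLUSIVE", "ENDPOINTS",
    "ASSAY_GROUPS", "AssayRecord", "EndpointLabelSet", "Exclusion",
    "IntegrationReport", "TaxonomyError",
    "classify_assay", "normalize_outcome", "vote_outcomes",
    "integrate_compound", "build_label_table", "summarize_labels",
    "read_assay_table", "write_label_table",
]

POSITIVE = "positive"
NEGATIVE = "negative"
INCONCLUSIVE = "inconclusive"

ENDPOINTS = ("Y1", "Y2", "Y3")

#: Closed assay taxonomy; extend via the ``extra`` argument of
#: :func:`classify_assay` / :func:`build_label_table`.
ASSAY_GROUPS: Mapping[str, str] = {
    "AMES": "Y1",
    "MN_VIVO": "Y2",       # mammalian erythrocyte micronucleus
    "BM_CA": "Y2",         # bone marrow chromosome aberration
    "VITRO_CA": "Y3",      # in vitro mammalian chromosomal aberration
    "TK": "Y3",            # in vitro TK gene mutation
    "SPERM_CA": "Y3",      # spermatocyte chromosome aberration
    "DOM_LETHAL": "Y3",    # rodent dominant lethal
    "HGPRT": "Y3",         # in vitro HGPRT gene mutation (supplement)
    "UDS": "Y3",           # unscheduled DNA synthesis (supplement)
    "SLRL": "Y3",          # Drosophila sex-linked recessive lethal (supplement)
}

_OUTCOME_ALIASES = {
    "positive": POSITIVE, "pos": POSITIVE, "1": POSITIVE, "+": POSITIVE,
    "negative": NEGATIVE, "neg": NEGATIVE, "0": NEGATIVE, "-": NEGATIVE,
    "inconclusive": INCONCLUSIVE, "equivocal": INCONCLUSIVE,
    "na": INCONCLUSIVE, "": INCONCLUSIVE,
}


class TaxonomyError(KeyError):
    """Raised for an assay code outside the known taxonomy."""


def normalize_outcome(raw) -> str:
    """Map an outcome spelling to positive / negative / inconclusive."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return INCONCLUSIVE
    key = str(raw).strip().lower()
    try:
        return _OUTCOME_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized assay outcome: {raw!r}") from None


def classify_assay(assay_code: str, extra: Mapping[str, str] | None = None) -> str:
    """Return the endpoint group (Y1/Y2/Y3) of an assay code."""
    code = str(assay_code).strip().upper()
    taxonomy = dict(ASSAY_GROUPS)
    if extra:
        for k, v in extra.items():
            if v not in ENDPOINTS:
                raise ValueError(f"extension group must be one of {ENDPOINTS}: {v!r}")
            taxonomy[str(k).strip().upper()] = v
    try:
        return taxonomy[code]
    except KeyError:
        raise TaxonomyError(f"unknown assay code: {code!r}") from None


@dataclass(frozen=True)
class AssayRecord:
    """One compound x assay x dichotomous-outcome observation."""
    compound_id: str
    assay_code: str
    outcome: str  # positive / negative / inconclusive

    def __post_init__(self):
        classify_assay(self.assay_code)
        if self.outcome not in (POSITIVE, NEGATIVE, INCONCLUSIVE):
            raise ValueError(f"invalid outcome state: {self.outcome!r}")


@dataclass(frozen=True)
class EndpointLabelSet:
    """Complete-case (Y1, Y2, Y3) binary labels for one compound."""
    compound_id: str
    y1: int
    y2: int
    y3: int


@dataclass(frozen=True)
class Exclusion:
    compound_id: str
    reason: str            # "missing_group" or "all_inconclusive"
    groups: tuple          # affected endpoint groups


@dataclass
class IntegrationReport:
    n_input_compounds: int = 0
    n_excluded_inconclusive: int = 0
    n_excluded_missing_group: int = 0
    n_complete: int = 0
    records_per_group: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def vote_outcomes(outcomes: Sequence[int]) -> int:
    """Majority vote over dichotomous outcomes; an exact tie is positive.

    ``outcomes`` must be non-empty 0/1 values with inconclusive records
    already removed.
    """
    if len(outcomes) == 0:
        raise ValueError("cannot vote on an empty outcome list")
    if any(o not in (0, 1) for o in outcomes):
        raise ValueError("outcomes must be 0/1; drop inconclusive records first")
    pos = sum(outcomes)
    neg = len(outcomes) - pos
    return 1 if pos >= neg else 0


def integrate_compound(records: Sequence[AssayRecord],
                       extra_taxonomy: Mapping[str, str] | None = None):
    """Fold one compound's assay records into an :class:`EndpointLabelSet`.

    Inconclusive records are dropped first; the remaining outcomes are
    grouped by endpoint and voted. If any of the three groups ends up with
    no usable record the compound is excluded — reason ``all_inconclusive``
    when the group had only inconclusive records, ``missing_group`` when it
    had none at all.
    """
    if not records:
        raise ValueError("no records supplied")
    cids = {r.compound_id for r in records}
    if len(cids) != 1:
        raise ValueError(f"records span multiple compounds: {sorted(cids)}")
    cid = records[0].compound_id

    usable: dict[str, list[int]] = {g: [] for g in ENDPOINTS}
    seen: set[str] = set()
    for r in records:
        g = classify_assay(r.assay_code, extra_taxonomy)
        seen.add(g)
        if r.outcome == INCONCLUSIVE:
            continue
        usable[g].append(1 if r.outcome == POSITIVE else 0)

    empty = tuple(g for g in ENDPOINTS if not usable[g])
    if empty:
        inconclusive_driven = tuple(g for g in empty if g in seen)
        if inconclusive_driven:
            return Exclusion(cid, "all_inconclusive", inconclusive_driven)
        return Exclusion(cid, "missing_group", empty)

    votes = {g: vote_outcomes(usable[g]) for g in ENDPOINTS}
    return EndpointLabelSet(cid, votes["Y1"], votes["Y2"], votes["Y3"])


def build_label_table(records: Iterable[AssayRecord],
                      extra_taxonomy: Mapping[str, str] | None = None):
    """Integrate all records into a complete-case label table.

    Returns ``(labels, report)`` where ``labels`` is a list of
    :class:`EndpointLabelSet` sorted by compound_id and ``report`` an
    :class:`IntegrationReport` whose exclusion counts reconcile with the
    input compound count.
    """
    by_compound: dict[str, list[AssayRecord]] = {}
    group_counts: Counter = Counter()
    for r in records:
        by_compound.setdefault(r.compound_id, []).append(r)
        group_counts[classify_assay(r.assay_code, extra_taxonomy)] += 1

    labels: list[EndpointLabelSet] = []
    report = IntegrationReport(
        n_input_compounds=len(by_compound),
        records_per_group=dict(sorted(group_counts.items())),
    )
    for cid in sorted(by_compound):
        out = integrate_compound(by_compound[cid], extra_taxonomy)
        if isinstance(out, EndpointLabelSet):
            labels.append(out)
            report.n_complete += 1
        elif out.reason == "all_inconclusive":
            report.n_excluded_inconclusive += 1
        else:
            report.n_excluded_missing_group += 1
    return labels, report


def labels_to_frame(labels: Sequence[EndpointLabelSet]) -> pd.DataFrame:
    """Label table as a DataFrame indexed by compound_id, columns Y1..Y3."""
    df = pd.DataFrame(
        [(l.compound_id, l.y1, l.y2, l.y3) for l in labels],
        columns=["compound_id", "Y1", "Y2", "Y3"],
    )
    return df.set_index("compound_id").sort_index()


def summarize_labels(labels, split_assignment: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Per-split, per-endpoint counts of positives/negatives and the
    positive rate ``100 * pos / (pos + neg)`` reported to two decimals.

    ``labels`` may be a list of :class:`EndpointLabelSet` or a label
    DataFrame; every compound must be assigned to exactly one split.
    """
    df = labels if isinstance(labels, pd.DataFrame) else labels_to_frame(labels)
    split = pd.Series(split_assignment)
    missing = df.index.difference(split.index)
    if len(missing):
        raise ValueError(f"compounds without a split assignment: {list(missing)[:5]}")

    rows = []
    for split_name in sorted(split.unique()):
        sub = df.loc[split.reindex(df.index) == split_name]
        for ep in ENDPOINTS:
            pos = int(sub[ep].sum())
            neg = int(len(sub) - pos)
            rate = round(100.0 * pos / (pos + neg), 2) if pos + neg else float("nan")
            rows.append((split_name, ep, pos, neg, rate))
    return pd.DataFrame(rows, columns=["split", "endpoint", "positive",
                                       "negative", "positive_rate"])


def positive_rate(positives: int, negatives: int) -> float:
    """``100 * positives / (positives + negatives)``, two decimals."""
    return round(100.0 * positives / (positives + negatives), 2)


def read_assay_table(path, extra_taxonomy=None) -> list[AssayRecord]:
    """Parse a long-format assay CSV/TSV with columns
    compound_id, assay_code, outcome (spellings normalized)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"compound_id", "assay_code", "outcome"}
    if not required.issubset(df.columns):
        raise ValueError(f"assay table must have columns {sorted(required)}; "
                         f"found {list(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        code = str(row.assay_code).strip().upper()
        classify_assay(code, extra_taxonomy)  # reject unknown codes at parse time
        records.append(AssayRecord(str(row.compound_id), code,
                                   normalize_outcome(row.outcome)))
    return records


def write_label_table(labels, path) -> None:
    labels_to_frame(labels).to_csv(path)
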