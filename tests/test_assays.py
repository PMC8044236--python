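"""Assay taxonomy, outcome voting and endpoint-group integration."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woeqsar.assays import (
    ASSAY_GROUPS, AssayRecord, EndpointLabelSet, Exclusion, TaxonomyError,
    build_label_table, classify_assay, integrate_compound, labels_to_frame,
    normalize_outcome, positive_rate, read_assay_table, summarize_labels,
    vote_outcomes,
)


def brute_force_vote(outcomes):
    """Independent oracle: count both classes, ties resolved positive."""
    pos = outcomes.count(1)
    neg = outcomes.count(0)
    if pos > neg:
        return 1
    if neg > pos:
        return 0
    return 1  # tie -> positive


class TestTaxonomy:
    @pytest.mark.parametrize("code,group", [
        ("AMES", "Y1"),
        ("MN_VIVO", "Y2"), ("BM_CA", "Y2"),
        ("VITRO_CA", "Y3"), ("TK", "Y3"), ("SPERM_CA", "Y3"),
        ("DOM_LETHAL", "Y3"), ("HGPRT", "Y3"), ("UDS", "Y3"), ("SLRL", "Y3"),
    ])
    def test_each_assay_maps_to_its_evidence_group(self, code, group):
        assert classify_assay(code) == group

    def test_mapping_is_total_over_the_taxonomy(self):
        assert all(classify_assay(c) in ("Y1", "Y2", "Y3") for c in ASSAY_GROUPS)

    def test_unknown_code_is_rejected_naming_the_code(self):
        with pytest.raises(TaxonomyError, match="COMET"):
            classify_assay("COMET")

    def test_taxonomy_extension_hook(self):
        assert classify_assay("COMET", extra={"COMET": "Y3"}) == "Y3"
        with pytest.raises(ValueError):
            classify_assay("COMET", extra={"COMET": "Y9"})

    @pytest.mark.parametrize("raw,expected", [
        ("Positive", "positive"), ("pos", "positive"), ("1", "positive"),
        ("+", "positive"), ("NEG", "negative"), ("0", "negative"),
        ("-", "negative"), ("equivocal", "inconclusive"), ("NA", "inconclusive"),
    ])
    def test_outcome_spellings_normalize_case_insensitively(self, raw, expected):
        assert normalize_outcome(raw) == expected

    def test_unknown_outcome_spelling_raises(self):
        with pytest.raises(ValueError):
            normalize_outcome("maybe")


class TestVoting:
    def test_tie_is_judged_positive(self):
        assert vote_outcomes([1, 0]) == 1

    def test_strict_majority_negative(self):
        assert vote_outcomes([0, 0, 1]) == 0

    def test_singleton(self):
        assert vote_outcomes([1]) == 1
        assert vote_outcomes([0]) == 0

    def test_agrees_with_bruteforce_oracle_up_to_length_six(self):
        for n in range(1, 7):
            for v in itertools.product((0, 1), repeat=n):
                assert vote_outcomes(list(v)) == brute_force_vote(list(v)), v

    def test_empty_vote_is_a_missing_data_error(self):
        with pytest.raises(ValueError):
            vote_outcomes([])

    def test_non_binary_outcomes_rejected(self):
        with pytest.raises(ValueError):
            vote_outcomes([1, 2])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=200)
    def test_permutation_invariance(self, v):
        assert vote_outcomes(v) == vote_outcomes(list(reversed(v)))
        assert vote_outcomes(v) == vote_outcomes(sorted(v))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=200)
    def test_flipping_a_negative_to_positive_is_monotone(self, v):
        before = vote_outcomes(v)
        for i, o in enumerate(v):
            if o == 0:
                flipped = v[:i] + [1] + v[i + 1:]
                assert vote_outcomes(flipped) >= before


def _rec(cid, code, outcome):
    return AssayRecord(cid, code, outcome)


class TestIntegrateCompound:
    def test_one_record_per_group(self):
        labels = integrate_compound([
            _rec("c1", "AMES", "positive"),
            _rec("c1", "MN_VIVO", "negative"),
            _rec("c1", "VITRO_CA", "negative"),
        ])
        assert labels == EndpointLabelSet("c1", 1, 0, 0)

    def test_missing_group_excludes_the_compound(self):
        out = integrate_compound([
            _rec("c1", "AMES", "positive"),
            _rec("c1", "MN_VIVO", "negative"),
        ])
        assert isinstance(out, Exclusion)
        assert out.reason == "missing_group"
        assert out.groups == ("Y3",)

    def test_group_with_only_inconclusive_records_is_excluded(self):
        out = integrate_compound([
            _rec("c1", "AMES", "inconclusive"),
            _rec("c1", "MN_VIVO", "negative"),
            _rec("c1", "TK", "positive"),
        ])
        assert isinstance(out, Exclusion)
        assert out.reason == "all_inconclusive"
        assert out.groups == ("Y1",)

    def test_within_group_voting_with_tie_positive(self):
        labels = integrate_compound([
            _rec("c1", "AMES", "positive"),
            _rec("c1", "MN_VIVO", "positive"),
            _rec("c1", "BM_CA", "negative"),       # Y2 tie -> positive
            _rec("c1", "TK", "negative"),
            _rec("c1", "UDS", "negative"),
            _rec("c1", "SLRL", "positive"),        # Y3 majority negative
        ])
        assert labels == EndpointLabelSet("c1", 1, 1, 0)

    def test_mixed_compound_ids_rejected(self):
        with pytest.raises(ValueError):
            integrate_compound([_rec("a", "AMES", "positive"),
                                _rec("b", "AMES", "positive")])


class TestBuildLabelTable:
    def test_exclusion_counts_reconcile(self):
        records = [
            _rec("a", "AMES", "positive"), _rec("a", "MN_VIVO", "negative"),
            _rec("a", "TK", "negative"),
            _rec("b", "AMES", "negative"), _rec("b", "TK", "positive"),  # no Y2
            _rec("c", "AMES", "positive"), _rec("c", "BM_CA", "positive"),
            _rec("c", "UDS", "positive"),
        ]
        labels, report = build_label_table(records)
        assert len(labels) == 2
        assert report.n_excluded_missing_group == 1
        assert (report.n_complete + report.n_excluded_missing_group
                + report.n_excluded_inconclusive == report.n_input_compounds)

    def test_empty_input_gives_empty_table(self):
        labels, report = build_label_table([])
        assert labels == [] and report.n_input_compounds == 0

    def test_output_sorted_and_complete(self, small_panel):
        _, records, _ = small_panel
        labels, report = build_label_table(records)
        ids = [l.compound_id for l in labels]
        assert ids == sorted(ids)
        assert (report.n_complete + report.n_excluded_inconclusive
                + report.n_excluded_missing_group == report.n_input_compounds)

    def test_exclusions_match_generator_bookkeeping(self, small_panel):
        """Compounds dropped for a missing group must be exactly those the
        generator removed a group from, plus all-inconclusive cases."""
        _, records, truth = small_panel
        labels, report = build_label_table(records)
        kept = {l.compound_id for l in labels}
        # every compound the generator left intact and with a usable record
        # per group must be retained unless inconclusive noise emptied a group
        assert report.n_excluded_missing_group >= 0
        missing_ids = set(truth.missing_group)
        assert kept.isdisjoint(missing_ids)
        n_other = report.n_input_compounds - len(missing_ids)
        assert report.n_complete == n_other - report.n_excluded_inconclusive


class TestSummarizeLabels:
    @staticmethod
    def _printed_panel():
        """Label table shaped like a published data distribution:
        train (230+, 302-), (296+, 236-), (282+, 250-);
        test (53+, 80-), (76+, 57-), (74+, 59-)."""
        rows, split = [], {}
        spec = {"train": (532, 230, 296, 282), "test": (133, 53, 76, 74)}
        i = 0
        for name, (n, p1, p2, p3) in spec.items():
            for j in range(n):
                cid = f"x{i:04d}"
                rows.append((cid, int(j < p1), int(j < p2), int(j < p3)))
                split[cid] = name
                i += 1
        df = pd.DataFrame(rows, columns=["compound_id", "Y1", "Y2", "Y3"])
        return df.set_index("compound_id"), pd.Series(split)

    def test_positive_rates_to_two_decimals(self):
        df, split = self._printed_panel()
        out = summarize_labels(df, split).set_index(["split", "endpoint"])
        assert out.loc[("train", "Y1"), "positive_rate"] == 43.23
        assert out.loc[("train", "Y2"), "positive_rate"] == 55.64
        assert out.loc[("train", "Y3"), "positive_rate"] == 53.01
        assert out.loc[("test", "Y1"), "positive_rate"] == 39.85
        assert out.loc[("test", "Y2"), "positive_rate"] == 57.14
        assert out.loc[("test", "Y3"), "positive_rate"] == 55.64

    def test_counts_partition_each_split(self):
        df, split = self._printed_panel()
        out = summarize_labels(df, split)
        for (name, _), grp in out.groupby(["split", "endpoint"]):
            total = int(grp["positive"].iloc[0] + grp["negative"].iloc[0])
            assert total == (split == name).sum()
        # column sums: train + test = total per endpoint
        tot = out.groupby("endpoint")[["positive", "negative"]].sum()
        assert tot.loc["Y1"].tolist() == [283, 382]
        assert tot.loc["Y2"].tolist() == [372, 293]
        assert tot.loc["Y3"].tolist() == [356, 309]

    def test_all_negative_split_rate_is_zero(self):
        assert positive_rate(0, 10) == 0.0

    def test_unassigned_compound_raises(self):
        df, split = self._printed_panel()
        with pytest.raises(ValueError):
            summarize_labels(df, split.iloc[:-1])


def test_assay_table_round_trip(tmp_path, small_panel):
    _, records, _ = small_panel
    path = tmp_path / "assays.csv"
    with open(path, "w") as fh:
        fh.write("compound_id,assay_code,outcome\n")
        for r in records:
            fh.write(f"{r.compound_id},{r.assay_code},{r.outcome}\n")
    back = read_assay_table(path)
    assert back == records


def test_label_frame_is_sorted_by_compound(small_panel):
    _, records, _ = small_panel
    labels, _ = build_label_table(records)
    df = labels_to_frame(labels)
    assert list(df.columns) == ["Y1", "Y2", "Y3"]
    assert df.index.is_monotonic_increasing
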