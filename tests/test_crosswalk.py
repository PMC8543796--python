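"""Crosswalk model: recode grammar, round-trip, prevalence, validation."""

import numpy as np
import pytest

from itemharmony.core import StudyDataset
from itemharmony.crosswalk import (
    Crosswalk,
    ItemMapping,
    item_prevalence,
    read_crosswalk,
    validate_crosswalk,
    write_crosswalk,
)
from itemharmony.errors import RecodeParseError, StructuralError
from itemharmony.standardize import RecodeRule


def _mapping(construct="delusion", study="A", var="v1", **kw):
    defaults = dict(
        construct_id=construct,
        study_id=study,
        source_variable=var,
        instrument="NPI",
        question_stem="does the participant believe others plan harm?",
        response_options=((1, "yes"), (5, "no")),
        missing_codes=frozenset({6, 96, 97, 98, 99}),
        recode=RecodeRule.parse("1->1;5->0;6,96,97,98,99->NA"),
    )
    defaults.update(kw)
    return ItemMapping(**defaults)


class TestRecodeGrammar:
    def test_survey_dialect_with_sentinels(self):
        rule = RecodeRule.parse("1->1;5->0;6,96,97,98,99->NA")
        assert rule.mapping[5] == 0
        assert rule.mapping[1] == 1
        assert rule.mapping[96] is None
        assert rule.declared_range == (0, 1)

    def test_round_trips_through_text(self):
        text = "1->3;2->2;3->1;4->0;-5->NA"
        rule = RecodeRule.parse(text)
        assert RecodeRule.parse(rule.to_text()) == rule

    @pytest.mark.parametrize(
        "bad", ["", "1->", "x->1", "1->y", "1->1;1->0", "1=1"]
    )
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(RecodeParseError):
            RecodeRule.parse(bad)

    def test_negative_harmonized_scores_rejected(self):
        with pytest.raises(RecodeParseError):
            RecodeRule.parse("1->-1")


class TestCrosswalkStructure:
    def test_two_rows_two_studies_one_construct(self, tmp_path):
        cw = Crosswalk([_mapping(study="A"), _mapping(study="B", var="v2")])
        assert len(cw) == 2
        assert cw.constructs == {"delusion"}
        assert cw.studies == {"A", "B"}

    def test_duplicate_pair_is_structural_error(self):
        with pytest.raises(StructuralError, match="delusion"):
            Crosswalk([_mapping(), _mapping(var="v9")])

    def test_duplicate_raw_code_across_options_and_missing(self):
        with pytest.raises(StructuralError, match="appear more than once"):
            _mapping(response_options=((1, "yes"), (96, "no")))

    def test_recode_must_cover_declared_codes(self):
        with pytest.raises(StructuralError, match="not total"):
            _mapping(recode=RecodeRule.parse("1->1;5->0"))

    def test_file_round_trip_is_identity(self, tmp_path):
        cw = Crosswalk(
            [
                _mapping(study="A"),
                _mapping(study="B", var="v2", gate_variable="v1"),
                _mapping(
                    construct="energy",
                    study="A",
                    var="v3",
                    is_summary_score=True,
                    response_options=((0, "none"), (1, "some"), (2, "lots")),
                    missing_codes=frozenset(),
                    recode=RecodeRule.parse("0->0;1->1;2->2"),
                ),
            ]
        )
        path = tmp_path / "cw.tsv"
        write_crosswalk(cw, path)
        assert read_crosswalk(path) == cw

    def test_parse_error_carries_cell_coordinates(self, tmp_path):
        path = tmp_path / "cw.tsv"
        write_crosswalk(Crosswalk([_mapping()]), path)
        text = path.read_text().replace("0,1", "0,x")  # corrupt the recode cell
        path.write_text(text.replace("1->1", "1->zz"))
        with pytest.raises(RecodeParseError, match="row 2"):
            read_crosswalk(path)


class TestItemPrevalence:
    def test_singletons(self):
        cw = Crosswalk(
            [_mapping(construct=c, study="A", var=f"v{i}") for i, c in enumerate("xyz")]
        )
        assert item_prevalence(cw) == {1: 3}

    def test_mixed_membership(self):
        cw = Crosswalk(
            [
                _mapping(construct="a", study="s1", var="v1"),
                _mapping(construct="a", study="s2", var="v2"),
                _mapping(construct="b", study="s1", var="v3"),
            ]
        )
        assert item_prevalence(cw) == {1: 1, 2: 1}

    def test_matches_brute_force_tally_on_random_membership(self):
        rng = np.random.default_rng(12345)
        studies = [f"s{k}" for k in range(5)]
        mappings = []
        membership = {}
        for i in range(10):
            k = int(rng.integers(1, 6))
            member = sorted(rng.choice(studies, size=k, replace=False))
            membership[f"c{i}"] = member
            for s in member:
                mappings.append(_mapping(construct=f"c{i}", study=s, var=f"v{i}_{s}"))
        cw = Crosswalk(mappings)
        # independent tally straight from the membership sets
        expected = {}
        for member in membership.values():
            expected[len(member)] = expected.get(len(member), 0) + 1
        assert item_prevalence(cw) == dict(sorted(expected.items()))
        assert sum(item_prevalence(cw).values()) == len(cw.constructs)


class TestValidateAgainstData:
    def _data(self, **items):
        n = len(next(iter(items.values())))
        return StudyDataset("A", list(range(n)), {k: np.asarray(v, float) for k, v in items.items()})

    def test_missing_variable_flagged(self):
        flags = validate_crosswalk(Crosswalk([_mapping()]), [self._data(other=[1, 5])])
        assert [f.kind for f in flags] == ["missing_variable"]

    def test_undeclared_code_flagged(self):
        flags = validate_crosswalk(Crosswalk([_mapping()]), [self._data(v1=[1, 5, 7])])
        assert [f.kind for f in flags] == ["undeclared_code"]
        assert flags[0].evidence["codes"] == [7]

    def test_consistent_pair_yields_no_flags(self):
        flags = validate_crosswalk(Crosswalk([_mapping()]), [self._data(v1=[1, 5, 96])])
        assert flags == []
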