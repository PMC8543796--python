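"""Comparability battery: sentinels, variability, ranges, polarity, gates."""

import numpy as np
import pytest

from itemharmony.core import StudyDataset
from itemharmony.crosswalk import Crosswalk, ItemMapping
from itemharmony.errors import StructuralError
from itemharmony.qc import (
    crosstab_ranges,
    detect_missing_codes,
    detect_no_variability,
    detect_reverse_candidates,
    endorsement_report,
    exclude_conditional,
    suggest_reversals,
)
from itemharmony.standardize import RecodeRule


def _ds(study="A", **items):
    n = len(next(iter(items.values())))
    return StudyDataset(study, list(range(n)), {k: np.asarray(v, float) for k, v in items.items()})


def _map(construct, study, var=None, gate="", levels=2):
    rule = ";".join(f"{k}->{k}" for k in range(levels))
    return ItemMapping(
        construct_id=construct,
        study_id=study,
        source_variable=var or f"{construct}_{study}",
        response_options=tuple((k, str(k)) for k in range(levels)),
        gate_variable=gate,
        recode=RecodeRule.parse(rule),
    )


class TestSentinelDetection:
    def test_high_range_skip_codes(self):
        flag = detect_missing_codes([1, 0, 96, 1], "c", "s")
        assert flag is not None and flag.evidence["suspect_codes"] == [96.0]

    def test_negative_cant_answer_code(self):
        flag = detect_missing_codes([1, 2, -5, 3])
        assert flag is not None and -5.0 in flag.evidence["suspect_codes"]

    def test_clean_binary_item_passes(self):
        assert detect_missing_codes([0, 1, 1, 0]) is None


class TestNoVariability:
    def test_constant_item_flagged(self):
        assert detect_no_variability([0, 0, 0]) is not None

    def test_varying_item_passes(self):
        assert detect_no_variability([0, 1]) is None

    def test_missing_ignored_when_rest_constant(self):
        flag = detect_no_variability([1, np.nan, 1])
        assert flag is not None and flag.evidence["constant_value"] == 1.0

    def test_all_missing_flagged_with_reason(self):
        flag = detect_no_variability([np.nan, np.nan])
        assert flag is not None and flag.evidence["reason"] == "all missing"


class TestCrosstabRanges:
    def test_binary_vs_four_level_discrepancy(self):
        cw = Crosswalk([_map("c1", "A"), _map("c1", "B", levels=4)])
        data = [_ds("A", c1=[0, 1, 0]), _ds("B", c1=[0, 1, 2, 3])]
        table, flags = crosstab_ranges(data, cw)
        assert len(table) == 2
        assert [f.construct_id for f in flags] == ["c1"]
        assert flags[0].evidence["ranges"] == {"A": [0.0, 1.0], "B": [0.0, 3.0]}

    def test_identical_ranges_not_flagged(self):
        cw = Crosswalk([_map("c1", "A"), _map("c1", "B")])
        data = [_ds("A", c1=[0, 1]), _ds("B", c1=[1, 0])]
        _, flags = crosstab_ranges(data, cw)
        assert flags == []

    def test_planted_mismatches_recovered_exactly(self):
        rng = np.random.default_rng(0)
        mismatched = {f"c{i:02d}" for i in rng.choice(40, size=20, replace=False)}
        mappings, data_a, data_b = [], {}, {}
        for i in range(40):
            c = f"c{i:02d}"
            hi = 3 if c in mismatched else 1
            mappings += [_map(c, "A"), _map(c, "B", levels=hi + 1)]
            data_a[c] = rng.integers(0, 2, size=30)
            data_b[c] = np.concatenate([[0, hi], rng.integers(0, hi + 1, size=28)])
        _, flags = crosstab_ranges([_ds("A", **data_a), _ds("B", **data_b)], Crosswalk(mappings))
        assert {f.construct_id for f in flags} == mismatched


class TestReverseCandidates:
    def test_hand_computed_truth_table(self):
        # A and B agree on every respondent; C is the complement of A
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        ds = _ds("A", ia=a, ib=a.copy(), ic=1 - a)
        flags = detect_reverse_candidates(ds, threshold=-0.2, min_overlap=4)
        flagged = {f.construct_id for f in flags}
        assert "ic" in flagged
        evid = {f.construct_id: f.evidence for f in flags}
        assert evid["ic"]["r"] == pytest.approx(-1.0)

    def test_aligned_items_not_flagged(self):
        rng = np.random.default_rng(1)
        theta = rng.standard_normal(300)
        items = {
            f"i{j}": (theta + rng.standard_normal(300) > 0).astype(float) for j in range(4)
        }
        assert detect_reverse_candidates(_ds("A", **items), min_overlap=10) == []

    def test_single_item_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert detect_reverse_candidates(_ds("A", only=[0, 1, 0])) == []

    def test_invariant_to_respondent_order(self):
        rng = np.random.default_rng(2)
        theta = rng.standard_normal(200)
        items = {
            "x": (theta > 0).astype(float),
            "y": (theta + rng.standard_normal(200) > 0).astype(float),
            "z": 1.0 - (theta > 0.2).astype(float),
        }
        ds = _ds("A", **items)
        perm = rng.permutation(200)
        ds_perm = _ds("A", **{k: v[perm] for k, v in items.items()})
        f1 = {(f.construct_id, round(f.evidence["r"], 12)) for f in detect_reverse_candidates(ds, min_overlap=10)}
        f2 = {(f.construct_id, round(f.evidence["r"], 12)) for f in detect_reverse_candidates(ds_perm, min_overlap=10)}
        assert f1 == f2


class TestSuggestReversals:
    def test_recovers_planted_minority_exactly(self, defect_bank):
        from itemharmony.standardize import apply_recode

        cw = defect_bank.crosswalk
        ds_raw = [d for d in defect_bank.datasets if d.study_id == "S2"][0]
        items = {
            m.construct_id: apply_recode(ds_raw.items[m.source_variable], m.recode)
            for m in cw.for_study("S2")
        }
        ds = StudyDataset("S2", list(ds_raw.respondent_ids), items)
        planted = sorted(
            c for c, s in defect_bank.truth["defects"]["reversed_in"] if s == "S2"
        )
        assert suggest_reversals(ds) == planted


class TestConditionalExclusion:
    def test_gated_severity_item_removed(self):
        cw = Crosswalk(
            [_map("present", "A"), _map("severity", "A", gate="present_A", levels=4)]
        )
        ds = _ds("A", present=[0, 1, 1], severity=[np.nan, 1, 2])
        out, flags = exclude_conditional(ds, cw)
        assert set(out.items) == {"present"}
        assert [(f.kind, f.construct_id) for f in flags] == [("conditional_item", "severity")]

    def test_no_gates_is_identity(self):
        cw = Crosswalk([_map("c1", "A"), _map("c2", "A")])
        ds = _ds("A", c1=[0, 1], c2=[1, 0])
        out, flags = exclude_conditional(ds, cw)
        assert flags == [] and set(out.items) == {"c1", "c2"}

    def test_gate_cycle_is_structural_error(self):
        cw = Crosswalk(
            [_map("x", "A", gate="y_A"), _map("y", "A", gate="x_A")]
        )
        ds = _ds("A", x=[0, 1], y=[1, 0])
        with pytest.raises(StructuralError, match="cycle"):
            exclude_conditional(ds, cw)

    def test_planted_gate_count(self, defect_bank, defect_pipeline):
        planted = {
            (f, s) for _, f, s in map(tuple, defect_bank.truth["defects"]["gated_pairs"])
        }
        flagged = {
            (f.construct_id, f.study_id)
            for f in defect_pipeline.flags
            if f.kind == "conditional_item"
        }
        assert flagged == planted


class TestEndorsementReport:
    def test_exact_counts_and_rates(self):
        rep = endorsement_report(_ds("A", i1=[0, 0, 1, np.nan]))
        row = rep.iloc[0]
        assert row["counts"] == {"0": 2, "1": 1}
        assert row["prop_missing"] == pytest.approx(0.25)
        assert row["endorsement"] == pytest.approx(1 / 3)

    def test_all_zero_item(self):
        rep = endorsement_report(_ds("A", i1=[0, 0, 0]))
        assert rep.iloc[0]["endorsement"] == 0.0

    def test_rare_item_rate_within_binomial_error(self):
        from itemharmony.irt import gauss_hermite_grid, model_probabilities
        from itemharmony.synthetic import GeneratorConfig, ItemSpec, generate

        a, b = 1.5, 3.2  # hard item: low marginal endorsement
        cfg = GeneratorConfig(
            studies=[("S1", 1000)],
            items=[
                ItemSpec("rare", a, b, ("S1",)),
                ItemSpec("f1", 1.2, 0.0, ("S1",)),
                ItemSpec("f2", 1.2, 0.5, ("S1",)),
            ],
            seed=99,
        )
        bank = generate(cfg)
        theta, w = gauss_hermite_grid(61)
        p_true = float(model_probabilities([a], [b], theta)[0] @ w)
        ds = bank.datasets[0]
        rep = endorsement_report(ds).set_index("item")
        observed = rep.loc["rare_s1", "endorsement"]
        se = np.sqrt(p_true * (1 - p_true) / 1000)
        assert abs(observed - p_true) < 3 * se
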