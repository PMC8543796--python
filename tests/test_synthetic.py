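"""Generator: statistical fidelity, determinism, detectable defects."""

import io

import numpy as np
import pytest

from itemharmony import synthetic
from itemharmony.core import write_study_data
from itemharmony.errors import ConfigError
from itemharmony.qc import detect_missing_codes, detect_reverse_candidates
from itemharmony.standardize import apply_recode
from itemharmony.synthetic import DefectPlan, GeneratorConfig, ItemSpec, generate


def _binary_items(n_items, studies, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ItemSpec(
            f"i{j:02d}",
            float(1 + 1.5 * rng.uniform()),
            float(-2 + 4 * rng.uniform()),
            studies,
        )
        for j in range(n_items)
    ]


class TestStatisticalFidelity:
    def test_median_difficulty_item_endorsed_half_the_time(self):
        """An item with b=0 under a standard-normal trait is endorsed with
        probability 1/2 by symmetry of the 2PL."""
        items = [ItemSpec("target", 1.5, 0.0, ("S1",))] + _binary_items(4, ("S1",), seed=3)
        bank = generate(GeneratorConfig(studies=[("S1", 2000)], items=items, seed=5))
        v = bank.datasets[0].items["target_s1"]
        se = np.sqrt(0.25 / 2000)
        assert abs(np.mean(v) - 0.5) < 3 * se

    def test_ordinal_items_span_declared_levels(self):
        items = [ItemSpec("ord", 1.5, 0.0, ("S1",), n_levels=4)] + _binary_items(3, ("S1",))
        bank = generate(GeneratorConfig(studies=[("S1", 2000)], items=items, seed=9))
        v = bank.datasets[0].items["ord_s1"]
        assert set(np.unique(v)) == {0.0, 1.0, 2.0, 3.0}


class TestDeterminism:
    def test_same_config_same_seed_byte_identical(self):
        cfg1 = synthetic.default_bank_config(seed=13, n_per_study=200)
        cfg2 = synthetic.default_bank_config(seed=13, n_per_study=200)
        b1, b2 = generate(cfg1), generate(cfg2)
        for d1, d2 in zip(b1.datasets, b2.datasets):
            s1, s2 = io.StringIO(), io.StringIO()
            write_study_data(d1, s1)
            write_study_data(d2, s2)
            assert s1.getvalue() == s2.getvalue()
        assert b1.truth == b2.truth

    def test_different_seed_changes_data(self):
        b1 = generate(synthetic.clean_bank_config(seed=1, n_per_study=100, n_items=4))
        b2 = generate(synthetic.clean_bank_config(seed=2, n_per_study=100, n_items=4))
        k = sorted(b1.datasets[0].items)[0]
        assert not np.array_equal(b1.datasets[0].items[k], b2.datasets[0].items[k])


class TestDefectsAreDetectable:
    def test_one_based_studies_have_minimum_one(self, defect_bank):
        for ds in defect_bank.datasets:
            if ds.study_id not in defect_bank.truth["defects"]["one_based"]:
                continue
            for name, v in ds.items.items():
                obs = v[~np.isnan(v)]
                clean = obs[(obs >= 0) & (obs < 90)]  # drop sentinel codes
                assert clean.min() >= 1

    def test_sentinel_injection_triggers_detection_rule(self, defect_bank):
        codes = defect_bank.truth["defects"]["sentinel_codes"]
        for ds in defect_bank.datasets:
            if ds.study_id not in codes:
                continue
            for name, v in ds.items.items():
                planted = set(codes[ds.study_id]) & set(np.unique(v[~np.isnan(v)]))
                if planted:
                    assert detect_missing_codes(v) is not None

    def test_planted_reversals_all_flagged(self, defect_bank):
        from itemharmony.core import StudyDataset

        cw = defect_bank.crosswalk
        planted = {
            (c, s) for c, s in map(tuple, defect_bank.truth["defects"]["reversed_in"])
        }
        studies = {s for _, s in planted}
        for study in studies:
            ds_raw = [d for d in defect_bank.datasets if d.study_id == study][0]
            items = {
                m.construct_id: apply_recode(ds_raw.items[m.source_variable], m.recode)
                for m in cw.for_study(study)
            }
            ds = StudyDataset(study, list(ds_raw.respondent_ids), items)
            flagged = {f.construct_id for f in detect_reverse_candidates(ds)}
            assert {c for c, s in planted if s == study} <= flagged

    def test_gated_follow_up_missing_iff_gate_closed(self, defect_bank):
        cw = defect_bank.crosswalk
        for gate_c, follow_c, study in map(tuple, defect_bank.truth["defects"]["gated_pairs"]):
            ds = [d for d in defect_bank.datasets if d.study_id == study][0]
            gate_m = cw.get(gate_c, study)
            follow_m = cw.get(follow_c, study)
            gate = apply_recode(ds.items[gate_m.source_variable], gate_m.recode)
            follow = apply_recode(ds.items[follow_m.source_variable], follow_m.recode)
            closed = gate == 0
            assert np.all(np.isnan(follow[closed]))
            fired_follow = follow[gate >= 1]
            assert np.nanmin(fired_follow) >= 1


class TestConfigValidation:
    def test_constant_plus_reversed_rejected(self):
        items = _binary_items(3, ("S1",))
        with pytest.raises(ConfigError, match="constant"):
            GeneratorConfig(
                studies=[("S1", 100)],
                items=items,
                defects=DefectPlan(
                    reversed_in=[("i00", "S1")], constant_in=[("i00", "S1")]
                ),
            ).validate()

    def test_unknown_study_reference_rejected(self):
        with pytest.raises(ConfigError, match="unknown study"):
            GeneratorConfig(
                studies=[("S1", 100)], items=_binary_items(3, ("S1",)),
                defects=DefectPlan(one_based=["S9"]),
            ).validate()

    def test_self_gating_rejected(self):
        items = _binary_items(3, ("S1",))
        with pytest.raises(ConfigError, match="gate"):
            GeneratorConfig(
                studies=[("S1", 100)], items=items,
                defects=DefectPlan(gated_pairs=[("i00", "i00", "S1")]),
            ).validate()


def test_round_trip_recovers_parameters(defect_bank):
    """generate -> recode with the truth (corrected) crosswalk -> fit
    recovers the planted discriminations and difficulties."""
    from itemharmony.core import StudyDataset
    from itemharmony.irt import fit_2pl

    cw = defect_bank.corrected_crosswalk()
    study = "S2"
    ds_raw = [d for d in defect_bank.datasets if d.study_id == study][0]
    skip = {c for c, s in map(tuple, defect_bank.truth["defects"]["constant_in"]) if s == study}
    names, cols, a_t, b_t = [], [], [], []
    for m in sorted(cw.for_study(study), key=lambda m: m.construct_id):
        info = defect_bank.truth["items"][m.construct_id]
        if m.construct_id in skip or info["n_levels"] != 2:
            continue
        names.append(m.construct_id)
        cols.append(apply_recode(ds_raw.items[m.source_variable], m.recode))
        a_t.append(info["a"])
        b_t.append(info["b"])
    X = np.column_stack(cols)
    fit = fit_2pl(X, item_names=names)
    assert np.sqrt(np.mean((fit.params.b - np.array(b_t)) ** 2)) < 0.2
    assert np.sqrt(np.mean((fit.params.a - np.array(a_t)) ** 2)) < 0.35
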