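"""Synthetic multi-study item banks with known truth and planted defects.

Real multi-study behavioral item banks are restricted-access; this module
generates stand-ins with the same pathologies so that every QC rule and
the IRT stage can be tested against a known ground truth. Responses follow
a unidimensional 2PL (binary) or a cumulative-logit graded mechanism
(ordinal) driven by a standard-normal latent trait; defects are applied
to the generated responses afterwards:

- reversed items: raw codes flipped in the named studies (polarity defect);
- one-based studies: every code shifted up by 1 (scale-origin defect);
- sentinel codes: a configured fraction of responses replaced by numeric
  missing-data codes (defaults 96-99 and -5, the dialects of common
  survey instruments);
- gated couplets: a follow-up severity item that is answered only when
  its gate item fires, missing otherwise (skip-pattern defect);
- constant items: overwritten with a constant (no-variability defect);
- couplet pairs: two items sharing an extra specific factor beyond the
  common trait (local-dependence defect).

Every defect is recorded in a truth record emitted alongside the data, so
the QC battery's output can be scored against it. Generation is fully
reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, StudyDataset, write_study_data
from .crosswalk import Crosswalk, ItemMapping, write_crosswalk
from .errors import ConfigError
from .standardize import RecodeRule

__all__ = [
    "ItemSpec",
    "DefectPlan",
    "GeneratorConfig",
    "GeneratedBank",
    "generate",
    "default_bank_config",
    "clean_bank_config",
    "write_bank",
]

#: default numeric missing-code dialects
SENTINELS_HIGH = (96, 97, 98, 99)
SENTINEL_NEGATIVE = (-5,)


@dataclass(frozen=True)
class ItemSpec:
    """One harmonized construct: its 2PL truth and study membership."""

    construct_id: str
    a: float  # discrimination
    b: float  # difficulty
    studies: tuple
    n_levels: int = 2  # 2 = binary; >2 = ordinal (graded mechanism)

    def __post_init__(self):
        if self.a <= 0:
            raise ConfigError(f"{self.construct_id}: discrimination must be positive")
        if self.n_levels < 2:
            raise ConfigError(f"{self.construct_id}: need at least 2 levels")
        object.__setattr__(self, "studies", tuple(self.studies))


@dataclass
class DefectPlan:
    reversed_in: list = field(default_factory=list)  # (construct, study)
    sentinel_codes: dict = field(default_factory=dict)  # study -> [codes]
    sentinel_rate: float = 0.05
    one_based: list = field(default_factory=list)  # studies
    gated_pairs: list = field(default_factory=list)  # (gate, follow, study)
    constant_in: list = field(default_factory=list)  # (construct, study)
    couplet_pairs: list = field(default_factory=list)  # (c1, c2, loading, study)


@dataclass
class GeneratorConfig:
    studies: list  # (study_id, n_respondents)
    items: list  # ItemSpec
    defects: DefectPlan = field(default_factory=DefectPlan)
    seed: int = 0

    def validate(self):
        study_ids = [s for s, _ in self.studies]
        if len(set(study_ids)) != len(study_ids):
            raise ConfigError("duplicate study ids")
        by_construct = {it.construct_id: it for it in self.items}
        if len(by_construct) != len(self.items):
            raise ConfigError("duplicate construct ids")
        for it in self.items:
            for s in it.studies:
                if s not in study_ids:
                    raise ConfigError(f"{it.construct_id}: unknown study {s!r}")
        d = self.defects

        def _check_pair(c, s, what):
            if c not in by_construct:
                raise ConfigError(f"{what}: unknown construct {c!r}")
            if s not in study_ids:
                raise ConfigError(f"{what}: unknown study {s!r}")
            if s not in by_construct[c].studies:
                raise ConfigError(f"{what}: {c!r} is not administered in {s!r}")

        for c, s in d.reversed_in:
            _check_pair(c, s, "reversed_in")
        for c, s in d.constant_in:
            _check_pair(c, s, "constant_in")
        overlap = set(map(tuple, d.reversed_in)) & set(map(tuple, d.constant_in))
        if overlap:
            raise ConfigError(
                f"item(s) {sorted(overlap)} planted as both constant and reversed; "
                f"a constant item has no polarity"
            )
        for s in d.one_based:
            if s not in study_ids:
                raise ConfigError(f"one_based: unknown study {s!r}")
        for s in d.sentinel_codes:
            if s not in study_ids:
                raise ConfigError(f"sentinel_codes: unknown study {s!r}")
        for g, f, s in d.gated_pairs:
            _check_pair(g, s, "gated_pairs gate")
            _check_pair(f, s, "gated_pairs follow")
            if g == f:
                raise ConfigError("a gate cannot gate itself")
        for c1, c2, _loading, s in d.couplet_pairs:
            _check_pair(c1, s, "couplet_pairs")
            _check_pair(c2, s, "couplet_pairs")


@dataclass
class GeneratedBank:
    datasets: list  # raw-coded StudyDatasets
    crosswalk: Crosswalk  # naive skeleton: defects NOT yet corrected
    truth: dict

    def corrected_crosswalk(self) -> Crosswalk:
        """Crosswalk with recode rules that undo the planted reversals.

        The naive skeleton reflects what a first-pass analyst would write
        before the directionality review; this variant represents the
        crosswalk after the reversal candidates have been confirmed.
        """
        reversed_pairs = {tuple(p) for p in self.truth["defects"]["reversed_in"]}
        mappings = []
        for m in self.crosswalk.mappings:
            if (m.construct_id, m.study_id) in reversed_pairs:
                n_levels = self.truth["items"][m.construct_id]["n_levels"]
                new_map = {}
                for code, target in m.recode.mapping.items():
                    new_map[code] = None if target is None else (n_levels - 1 - target)
                m = ItemMapping(
                    construct_id=m.construct_id,
                    study_id=m.study_id,
                    source_variable=m.source_variable,
                    instrument=m.instrument,
                    question_stem=m.question_stem,
                    response_options=m.response_options,
                    missing_codes=m.missing_codes,
                    gate_variable=m.gate_variable,
                    is_summary_score=m.is_summary_score,
                    recode=RecodeRule(new_map),
                )
            mappings.append(m)
        return Crosswalk(mappings)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _graded_levels(a, b, n_levels):
    """Cumulative-logit thresholds, centered on b with fixed spacing."""
    offsets = (np.arange(1, n_levels) - n_levels / 2.0) * 0.8
    return b + offsets


def generate(config: GeneratorConfig) -> GeneratedBank:
    """Generate the bank: raw-coded study datasets, crosswalk skeleton, truth.

    The crosswalk skeleton declares response options, sentinel missing
    codes, gate variables and recode rules that undo the coding-dialect
    defects (sentinels to missing, one-based shift) but NOT the planted
    reversals -- those are what the directionality check is for; use
    :meth:`GeneratedBank.corrected_crosswalk` for the post-review rules.
    """
    config.validate()
    d = config.defects
    reversed_set = {tuple(p) for p in d.reversed_in}
    constant_set = {tuple(p) for p in d.constant_in}
    gated = {(f, s): g for g, f, s in d.gated_pairs}

    datasets = []
    mappings = []
    for s_idx, (study, n) in enumerate(config.studies):
        rng = np.random.default_rng([config.seed, s_idx])
        theta = rng.standard_normal(n)
        shift = 1 if study in d.one_based else 0
        study_items = [it for it in config.items if study in it.studies]
        # shared specific factors for planted couplets in this study
        couplet_u = {}
        for c1, c2, loading, cs in d.couplet_pairs:
            if cs == study:
                u = rng.standard_normal(n)
                gamma = 1.702 * loading / np.sqrt(max(1.0 - loading**2, 1e-9))
                couplet_u[c1] = couplet_u.get(c1, 0.0) + gamma * u
                couplet_u[c2] = couplet_u.get(c2, 0.0) + gamma * u

        clean = {}
        for it in study_items:
            extra = couplet_u.get(it.construct_id, 0.0)
            u = rng.uniform(size=n)
            if it.n_levels == 2:
                p = _logistic(it.a * (theta - it.b) + extra)
                y = (u < p).astype(float)
            else:
                thr = _graded_levels(it.a, it.b, it.n_levels)
                # cumulative sampling: y counts how many thresholds are passed
                y = np.zeros(n)
                for t in thr:
                    y += (u < _logistic(it.a * (theta - t) + extra)).astype(float)
            clean[it.construct_id] = y

        raw = {}
        for it in study_items:
            c = it.construct_id
            y = clean[c].copy()
            if (c, study) in constant_set:
                y[:] = 0.0
            if (c, study) in reversed_set:
                y = (it.n_levels - 1) - y
            if (c, study) in gated:
                gate_c = gated[(c, study)]
                gate_val = clean[gate_c]
                fired = gate_val >= 1
                y = np.where(fired, np.maximum(y, 1.0), MISSING)
            y = y + shift
            raw[c] = y

        # sentinel injection, after all coding defects
        codes = d.sentinel_codes.get(study)
        if codes:
            for it in study_items:
                y = raw[it.construct_id]
                hit = rng.uniform(size=n) < d.sentinel_rate
                y[hit] = rng.choice(codes, size=int(hit.sum()))

        items_out = {}
        for it in study_items:
            var = f"{it.construct_id}_{study.lower()}"
            items_out[var] = raw[it.construct_id]
            mappings.append(
                _make_mapping(it, study, var, shift, codes or (), gated, study_items)
            )
        datasets.append(StudyDataset(study, list(range(1, n + 1)), items_out))

    truth = {
        "seed": config.seed,
        "studies": {s: n for s, n in config.studies},
        "items": {
            it.construct_id: {
                "a": it.a,
                "b": it.b,
                "n_levels": it.n_levels,
                "studies": list(it.studies),
            }
            for it in config.items
        },
        "defects": {
            "reversed_in": [list(p) for p in d.reversed_in],
            "sentinel_codes": {s: list(c) for s, c in d.sentinel_codes.items()},
            "sentinel_rate": d.sentinel_rate,
            "one_based": list(d.one_based),
            "gated_pairs": [list(p) for p in d.gated_pairs],
            "constant_in": [list(p) for p in d.constant_in],
            "couplet_pairs": [list(p) for p in d.couplet_pairs],
        },
    }
    return GeneratedBank(datasets, Crosswalk(mappings), truth)


def _make_mapping(it, study, var, shift, sentinel_codes, gated, study_items):
    levels = list(range(shift, it.n_levels + shift))
    options = tuple((code, f"level {code - shift}") for code in levels)
    recode = {code: code - shift for code in levels}
    for sc in sentinel_codes:
        recode[int(sc)] = None
    gate_var = ""
    key = (it.construct_id, study)
    if key in gated:
        gate_c = gated[key]
        gate_var = f"{gate_c}_{study.lower()}"
    return ItemMapping(
        construct_id=it.construct_id,
        study_id=study,
        source_variable=var,
        instrument="SYNB" if it.n_levels == 2 else "SYNL",
        question_stem=f"synthetic item {it.construct_id}",
        response_options=options,
        missing_codes=frozenset(int(c) for c in sentinel_codes),
        gate_variable=gate_var,
        is_summary_score=False,
        recode=RecodeRule(recode),
    )


def default_bank_config(seed: int = 0, n_per_study: int = 1000) -> GeneratorConfig:
    """A three-study bank planting every defect class.

    Twelve shared binary items with discriminations in [1, 2.5] and
    difficulties in [-2, 2], plus two ordinal items and two gated
    follow-ups. Study S1 uses 96-99 sentinels and hosts the skip patterns
    and a local-dependence couplet; S2 plants four reversed items and one
    constant item; S3 is one-based with a -5 sentinel.
    """
    studies = [("S1", n_per_study), ("S2", n_per_study), ("S3", n_per_study)]
    all3 = ("S1", "S2", "S3")
    rng = np.random.default_rng(seed)
    items = []
    for j in range(12):
        a = float(np.round(1.0 + 1.5 * rng.uniform(), 3))
        b = float(np.round(-2.0 + 4.0 * rng.uniform(), 3))
        items.append(ItemSpec(f"itm{j:02d}", a, b, all3))
    items.append(ItemSpec("ord00", 1.5, 0.0, ("S1", "S3"), n_levels=4))
    items.append(ItemSpec("ord01", 1.2, 0.5, ("S2", "S3"), n_levels=4))
    # gated severity follow-ups, administered in S1 only
    items.append(ItemSpec("sev00", 1.3, 0.0, ("S1",), n_levels=4))
    items.append(ItemSpec("sev01", 1.1, 0.3, ("S1",), n_levels=4))
    defects = DefectPlan(
        reversed_in=[("itm01", "S2"), ("itm04", "S2"), ("itm07", "S2"), ("itm10", "S2")],
        sentinel_codes={"S1": list(SENTINELS_HIGH), "S3": list(SENTINEL_NEGATIVE)},
        sentinel_rate=0.05,
        one_based=["S3"],
        gated_pairs=[("itm00", "sev00", "S1"), ("itm03", "sev01", "S1")],
        constant_in=[("itm11", "S2")],
        couplet_pairs=[("itm05", "itm06", 0.6, "S1")],
    )
    return GeneratorConfig(studies=studies, items=items, defects=defects, seed=seed)


def clean_bank_config(
    seed: int = 0,
    n_per_study: int = 1000,
    n_items: int = 15,
    n_studies: int = 1,
) -> GeneratorConfig:
    """A defect-free bank of binary items: the null condition.

    Item truth spans discriminations [1, 2.5] and difficulties [-2, 2].
    """
    studies = [(f"S{k + 1}", n_per_study) for k in range(n_studies)]
    ids = tuple(s for s, _ in studies)
    rng = np.random.default_rng(seed)
    items = [
        ItemSpec(
            f"itm{j:02d}",
            float(np.round(1.0 + 1.5 * rng.uniform(), 3)),
            float(np.round(-2.0 + 4.0 * rng.uniform(), 3)),
            ids,
        )
        for j in range(n_items)
    ]
    return GeneratorConfig(studies=studies, items=items, seed=seed)


def write_bank(bank: GeneratedBank, outdir, delimiter: str = "\t") -> dict:
    """Write study tables, crosswalk skeleton, and truth record to a directory.

    Returns the mapping of logical names to paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for ds in bank.datasets:
        p = os.path.join(outdir, f"{ds.study_id}.tsv")
        write_study_data(ds, p, delimiter=delimiter)
        paths[ds.study_id] = p
    cw_path = os.path.join(outdir, "crosswalk.tsv")
    write_crosswalk(bank.crosswalk, cw_path, delimiter=delimiter)
    paths["crosswalk"] = cw_path
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(bank.truth, fh, indent=2, sort_keys=True)
    paths["truth"] = truth_path
    return paths
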