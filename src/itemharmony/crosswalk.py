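"""The crosswalk: the table linking harmonized constructs to study variables.

A crosswalk has one row per (construct, study) pair and carries, for each
item, the source variable name, instrument, question stem, response
options, declared missing codes, any gate (skip-pattern) variable, a
summary-score marker, and a declarative recode rule. It is the single
human-edited artifact from which every downstream transform is derived.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import QCFlag, StudyDataset, is_missing
from .errors import RecodeParseError, StructuralError
from .standardize import RecodeRule

__all__ = [
    "ItemMapping",
    "Crosswalk",
    "read_crosswalk",
    "write_crosswalk",
    "item_prevalence",
    "validate_crosswalk",
    "CROSSWALK_COLUMNS",
]

CROSSWALK_COLUMNS = [
    "construct_id",
    "study_id",
    "source_variable",
    "instrument",
    "question_stem",
    "response_options",
    "missing_codes",
    "gate_variable",
    "is_summary_score",
    "recode",
]


@dataclass(frozen=True)
class ItemMapping:
    """One crosswalk row: a harmonized construct in one study."""

    construct_id: str
    study_id: str
    source_variable: str
    instrument: str = ""
    question_stem: str = ""
    response_options: tuple = ()  # ordered ((raw_code, label), ...)
    missing_codes: frozenset = frozenset()
    gate_variable: str = ""  # empty -> unconditional
    is_summary_score: bool = False
    recode: RecodeRule = field(default_factory=lambda: RecodeRule({0: 0, 1: 1}))

    def __post_init__(self):
        object.__setattr__(
            self, "response_options", tuple((int(c), str(l)) for c, l in self.response_options)
        )
        object.__setattr__(self, "missing_codes", frozenset(int(c) for c in self.missing_codes))
        seen = Counter(c for c, _ in self.response_options)
        seen.update(self.missing_codes)
        dupes = [c for c, k in seen.items() if k > 1]
        if dupes:
            raise StructuralError(
                f"({self.construct_id}, {self.study_id}): raw code(s) {sorted(dupes)} "
                f"appear more than once across response_options and missing_codes"
            )
        declared = set(seen)
        undeclared = declared - set(self.recode.domain)
        if declared and undeclared:
            raise StructuralError(
                f"({self.construct_id}, {self.study_id}): recode rule is not total; "
                f"declared code(s) {sorted(undeclared)} have no recode clause"
            )

    @property
    def declared_codes(self) -> frozenset:
        return frozenset(c for c, _ in self.response_options) | self.missing_codes


@dataclass
class Crosswalk:
    """A validated collection of item mappings.

    (construct_id, study_id) pairs are unique; ``constructs`` and
    ``studies`` are derived from the mappings.
    """

    mappings: list

    def __post_init__(self):
        pairs = Counter((m.construct_id, m.study_id) for m in self.mappings)
        dupes = [p for p, k in pairs.items() if k > 1]
        if dupes:
            raise StructuralError(
                f"duplicate (construct, study) pair(s): {sorted(dupes)}; each pair "
                f"may appear on at most one crosswalk row"
            )

    @property
    def constructs(self) -> set:
        return {m.construct_id for m in self.mappings}

    @property
    def studies(self) -> set:
        return {m.study_id for m in self.mappings}

    def for_study(self, study_id: str) -> list:
        return [m for m in self.mappings if m.study_id == study_id]

    def get(self, construct_id: str, study_id: str) -> ItemMapping:
        for m in self.mappings:
            if m.construct_id == construct_id and m.study_id == study_id:
                return m
        raise KeyError((construct_id, study_id))

    def __len__(self):
        return len(self.mappings)

    def __eq__(self, other):
        if not isinstance(other, Crosswalk):
            return NotImplemented
        return self.mappings == other.mappings


def _fmt_options(options) -> str:
    return "|".join(f"{code}={label}" for code, label in options)


def _parse_options(text: str, row=None):
    text = text.strip()
    if not text:
        return ()
    out = []
    for part in text.split("|"):
        if "=" not in part:
            raise RecodeParseError(
                f"response option {part!r} lacks 'code=label'", row=row, column="response_options"
            )
        code, label = part.split("=", 1)
        try:
            out.append((int(code.strip()), label.strip()))
        except ValueError:
            raise RecodeParseError(
                f"response-option code {code!r} is not an integer",
                row=row,
                column="response_options",
            ) from None
    return tuple(out)


def read_crosswalk(path, delimiter: str = "\t") -> Crosswalk:
    """Read and validate a crosswalk file.

    The file is delimited text with a header row carrying the canonical
    column names. Recode cells use the compact grammar, e.g.
    ``"1->1;5->0;6,96,97,98,99->NA"``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CROSSWALK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise StructuralError(f"{path}: missing crosswalk column(s) {missing_cols}")
    mappings = []
    for i, row in df.iterrows():
        try:
            rule = RecodeRule.parse(row["recode"])
        except RecodeParseError as exc:
            raise RecodeParseError(str(exc), row=int(i) + 2, column="recode") from None
        mc = row["missing_codes"].strip()
        try:
            missing_codes = frozenset(int(t) for t in mc.split(",") if t.strip()) if mc else frozenset()
        except ValueError:
            raise RecodeParseError(
                "missing_codes must be comma-separated integers",
                row=int(i) + 2,
                column="missing_codes",
            ) from None
        mappings.append(
            ItemMapping(
                construct_id=row["construct_id"].strip(),
                study_id=row["study_id"].strip(),
                source_variable=row["source_variable"].strip(),
                instrument=row["instrument"].strip(),
                question_stem=row["question_stem"],
                response_options=_parse_options(row["response_options"], row=int(i) + 2),
                missing_codes=missing_codes,
                gate_variable=row["gate_variable"].strip(),
                is_summary_score=row["is_summary_score"].strip().lower() in {"1", "true", "yes"},
                recode=rule,
            )
        )
    return Crosswalk(mappings)


def write_crosswalk(cw: Crosswalk, path, delimiter: str = "\t") -> None:
    """Serialize a crosswalk so that reading it back reproduces it exactly."""
    rows = []
    for m in cw.mappings:
        rows.append(
            {
                "construct_id": m.construct_id,
                "study_id": m.study_id,
                "source_variable": m.source_variable,
                "instrument": m.instrument,
                "question_stem": m.question_stem,
                "response_options": _fmt_options(m.response_options),
                "missing_codes": ",".join(str(c) for c in sorted(m.missing_codes)),
                "gate_variable": m.gate_variable,
                "is_summary_score": "1" if m.is_summary_score else "0",
                "recode": m.recode.to_text(),
            }
        )
    pd.DataFrame(rows, columns=CROSSWALK_COLUMNS).to_csv(path, sep=delimiter, index=False)


def item_prevalence(cw: Crosswalk) -> dict:
    """How many constructs appear in exactly k studies, for each k.

    Returns ``{k: count}``; counts sum to the number of distinct constructs.
    """
    per_construct = Counter(m.construct_id for m in cw.mappings)
    out = Counter(per_construct.values())
    return dict(sorted(out.items()))


def validate_crosswalk(cw: Crosswalk, datasets) -> list:
    """Cross-check the crosswalk against raw study data.

    Emits ``missing_variable`` flags for source or gate variables absent
    from the named study's columns, and ``undeclared_code`` flags for raw
    codes observed in the data but not declared in the mapping's response
    options or missing codes. Findings are flags, never exceptions.
    """
    by_study = {ds.study_id: ds for ds in datasets}
    missing_studies = cw.studies - set(by_study)
    if missing_studies:
        raise StructuralError(
            f"no dataset supplied for study(ies) {sorted(missing_studies)}"
        )
    flags = []
    for m in cw.mappings:
        ds = by_study[m.study_id]
        if m.source_variable not in ds.items:
            flags.append(
                QCFlag(
                    "missing_variable",
                    m.construct_id,
                    m.study_id,
                    {"variable": m.source_variable, "role": "source"},
                )
            )
            continue
        if m.gate_variable and m.gate_variable not in ds.items:
            flags.append(
                QCFlag(
                    "missing_variable",
                    m.construct_id,
                    m.study_id,
                    {"variable": m.gate_variable, "role": "gate"},
                )
            )
        raw = ds.items[m.source_variable]
        obs = raw[~is_missing(raw)]
        observed_codes = {int(u) for u in np.unique(obs) if u == round(u)}
        undeclared = sorted(observed_codes - set(m.declared_codes))
        if undeclared:
            flags.append(
                QCFlag(
                    "undeclared_code",
                    m.construct_id,
                    m.study_id,
                    {"codes": [int(c) for c in undeclared]},
                )
            )
    return flags
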